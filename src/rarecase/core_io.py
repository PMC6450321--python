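"""Domain containers and file I/O for the case-only rare-variant pipeline.

The pipeline operates on four kinds of input: a VCF with per-sample GT
genotypes, a variant annotation table (sidecar TSV or SnpEff-style ANN INFO
field), a phenotype/covariate TSV, and gene lists / GMT pathway sets / 6-column
PED pedigrees.  Everything downstream works on the containers defined here,
chiefly :class:`GenotypeMatrix` (samples x variants ALT-dosage codes).

Conventions
-----------
* Coordinates are 1-based VCF positions; a variant is keyed by the string
  ``"chrom:pos:ref:alt"``.
* Multiallelic VCF records are decomposed into one biallelic record per ALT
  before any downstream use.
* Half-calls (``./1``) are treated as missing — a missing call is never
  evidence of carrying an allele.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

PIPELINE_VERSION = "rarecase 0.1.0"

MISSING = -1
IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class VcfParseError(ParseError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant: one REF and exactly one ALT allele."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt identical at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeMatrix:
    """Samples x variants ALT-allele dosage codes in {0, 1, 2, MISSING}."""

    sample_ids: list[str]
    variant_keys: list[str]
    dosage: np.ndarray  # int8, shape (n_samples, n_variants), MISSING == -1

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_keys)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_keys)} variants"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid dosage codes: {np.unique(self.dosage[bad])}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def column(self, key: str) -> np.ndarray:
        return self.dosage[:, self.variant_keys.index(key)]

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return GenotypeMatrix(list(ids), list(self.variant_keys), self.dosage[idx])

    def subset_variants(self, keys: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variant_keys.index(k) for k in keys]
        return GenotypeMatrix(list(self.sample_ids), list(keys), self.dosage[:, idx])

    def alt_freqs(self) -> np.ndarray:
        """Per-variant ALT allele frequency over called genotypes."""
        called = self.dosage != MISSING
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        denom = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, alt / np.maximum(denom, 1), np.nan)

    def mafs(self) -> np.ndarray:
        p = self.alt_freqs()
        return np.minimum(p, 1 - p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.variant_keys)


@dataclass(frozen=True)
class Annotation:
    """Functional annotation of one (variant, gene) pair."""

    variant_key: str
    gene: str
    consequence: str
    impact: str
    pop_af: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.impact not in IMPACT_CLASSES:
            raise ValueError(
                f"impact {self.impact!r} not one of {IMPACT_CLASSES} "
                f"(variant {self.variant_key})"
            )
        for pop, af in self.pop_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {af} for {pop} outside [0, 1]")


@dataclass
class SampleRecord:
    """Phenotype and covariates for one sequenced individual."""

    sample_id: str
    status: str  # "case" | "control"
    sex: str = "unknown"
    age: float = float("nan")
    center: str = "NA"
    pcs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cluster: str | None = None

    def __post_init__(self):
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be case/control, got {self.status!r}")
        self.pcs = np.asarray(self.pcs, dtype=float)
        if self.pcs.size and not np.isfinite(self.pcs).all():
            raise ValueError(f"non-finite principal components for {self.sample_id}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PedigreeMember:
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"
    affected: str  # "yes" | "no" | "unknown"
    genotyped: bool = True


@dataclass
class Pedigree:
    family_id: str
    members: list[PedigreeMember]

    def __post_init__(self):
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate individual ids in family {self.family_id}")
        known = set(ids)
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in known:
                    raise ValueError(
                        f"family {self.family_id}: parent {parent} of "
                        f"{m.individual_id} is not a member"
                    )
        self._check_acyclic()

    def _check_acyclic(self):
        parents = {
            m.individual_id: [p for p in (m.father_id, m.mother_id) if p is not None]
            for m in self.members
        }
        state: dict[str, int] = {}

        def visit(node: str):
            if state.get(node) == 1:
                raise ValueError(f"pedigree loop in family {self.family_id} at {node}")
            if state.get(node) == 2:
                return
            state[node] = 1
            for p in parents[node]:
                visit(p)
            state[node] = 2

        for m in self.members:
            visit(m.individual_id)

    def member(self, individual_id: str) -> PedigreeMember:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        raise KeyError(individual_id)

    def founders(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]

    def affected_members(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.affected == "yes"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


def read_vcf(path, region: str | None = None) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read a VCF 4.x file (optionally gzipped) into decomposed biallelic records.

    Multiallelic sites are split into one :class:`VariantRecord` per ALT allele;
    the per-sample dosage for each ALT counts only that allele, so the per-ALT
    dosages of a decomposed site sum to the original ALT count.  ``./.`` and
    half-calls become :data:`MISSING`; phase separators are ignored.
    """
    path = str(path)
    chrom = lo = hi = None
    if region is not None:
        m = _REGION_RE.match(region)
        if m is None:
            raise ValueError(f"malformed region {region!r}; expected chrom[:start-end]")
        chrom = m.group(1)
        if m.group(2):
            lo, hi = int(m.group(2)), int(m.group(3))

    try:
        vcf = VCF(path, gts012=False)
        samples = list(vcf.samples)
        variants: list[VariantRecord] = []
        columns: list[np.ndarray] = []
        for var in vcf:
            if chrom is not None and var.CHROM != chrom:
                continue
            if lo is not None and not (lo <= var.POS <= hi):
                continue
            if not var.ALT:
                continue
            gts = var.genotypes  # [[a0, a1, phased], ...]
            a = np.array([[g[0], g[1]] for g in gts], dtype=np.int16)
            miss = (a < 0).any(axis=1)  # half-calls count as missing
            for alt_idx, alt in enumerate(var.ALT):
                code = alt_idx + 1
                dose = (a == code).sum(axis=1).astype(np.int8)
                dose[miss] = MISSING
                variants.append(
                    VariantRecord(var.CHROM, var.POS, var.ID or ".", var.REF, alt)
                )
                columns.append(dose)
    except ParseError:
        raise
    except Exception as exc:  # htslib errors do not carry line numbers
        raise VcfParseError(f"failed to parse VCF {path}: {exc}") from exc

    dosage = (
        np.stack(columns, axis=1) if columns else np.zeros((len(samples), 0), np.int8)
    )
    gm = GenotypeMatrix(samples, [v.key for v in variants], dosage)
    return variants, gm


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path, variants: Sequence[VariantRecord], genotypes: GenotypeMatrix,
              extra_header: Iterable[str] = ()) -> None:
    """Write biallelic records plus GT dosages as uncompressed VCF 4.2."""
    if [v.key for v in variants] != list(genotypes.variant_keys):
        raise ValueError("variant records do not match genotype matrix columns")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={PIPELINE_VERSION}\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        for chrom in dict.fromkeys(v.chrom for v in variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j, v in enumerate(variants):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in genotypes.dosage[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_ANN_IMPACTS = set(IMPACT_CLASSES)


def read_annotations(path, dialect: str = "tsv") -> list[Annotation]:
    """Read per-(variant, gene) annotations.

    ``tsv``: header columns ``variant_key, gene, consequence, impact`` plus any
    number of ``AF_<pop>`` allele-frequency columns.  ``vcf_ann``: parse a
    SnpEff-style ``ANN=`` INFO field (``allele|consequence|impact|gene|...``)
    from a VCF; ``AF_<pop>`` INFO keys become population frequencies.
    """
    if dialect == "tsv":
        return _read_annotations_tsv(path)
    if dialect == "vcf_ann":
        return _read_annotations_vcf(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_annotations_tsv(path) -> list[Annotation]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["variant_key", "gene", "consequence", "impact"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"annotation TSV {path} missing column(s): {', '.join(missing)}")
    af_cols = [c for c in df.columns if c.startswith("AF_")]
    out = []
    for row in df.itertuples(index=False):
        pop_af = {}
        for c in af_cols:
            val = getattr(row, c)
            if pd.notna(val) and str(val) != "":
                pop_af[c[3:]] = float(val)
        out.append(
            Annotation(row.variant_key, row.gene, row.consequence, row.impact, pop_af)
        )
    return out


def _read_annotations_vcf(path) -> list[Annotation]:
    out = []
    vcf = VCF(str(path))
    for var in vcf:
        ann = var.INFO.get("ANN")
        if ann is None:
            continue
        pop_af = {
            k[3:]: float(v)
            for k, v in dict(var.INFO).items()
            if k.startswith("AF_")
        }
        for entry in str(ann).split(","):
            fields = entry.split("|")
            if len(fields) < 4:
                raise ParseError(f"malformed ANN entry {entry!r} at {var.CHROM}:{var.POS}")
            allele, consequence, impact, gene = fields[:4]
            consequence = consequence.split("&")[0]
            key = f"{var.CHROM}:{var.POS}:{var.REF}:{allele}"
            out.append(Annotation(key, gene, consequence, impact, pop_af))
    return out


# ---------------------------------------------------------------------------
# phenotypes / gene sets / pedigrees
# ---------------------------------------------------------------------------


def read_phenotypes(path, status_coding: str = "strings") -> list[SampleRecord]:
    """Read the sample phenotype/covariate TSV.

    ``status_coding="strings"`` expects case/control literals; ``"plink"``
    maps 2 -> case and 1 -> control.  Principal components are taken from
    columns named ``PC1, PC2, ...``; an optional ``cluster`` column is carried
    through.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["sample_id", "status", "sex", "age", "center"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"phenotype TSV {path} missing column(s): {', '.join(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"duplicate sample ids in {path}: {dups}")
    pc_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"PC\d+", c)),
        key=lambda c: int(c[2:]),
    )
    records = []
    for row in df.itertuples(index=False):
        status = row.status
        if status_coding == "plink":
            status = {"2": "case", "1": "control"}.get(str(status), status)
        pcs = np.array([float(getattr(row, c)) for c in pc_cols])
        cluster = getattr(row, "cluster", None)
        records.append(
            SampleRecord(
                row.sample_id,
                status,
                sex=row.sex,
                age=float(row.age),
                center=row.center,
                pcs=pcs,
                cluster=None if cluster in (None, "", "NA") or pd.isna(cluster) else cluster,
            )
        )
    return records


def write_phenotypes(path, samples: Sequence[SampleRecord]) -> None:
    n_pcs = max((s.pcs.size for s in samples), default=0)
    cols = ["sample_id", "status", "sex", "age", "center"]
    cols += [f"PC{i + 1}" for i in range(n_pcs)]
    cols += ["cluster"]
    with open(path, "w") as fh:
        fh.write(f"# {PIPELINE_VERSION}\n")
        fh.write("\t".join(cols) + "\n")
        for s in samples:
            pcs = [f"{s.pcs[i]:.6g}" if i < s.pcs.size else "0" for i in range(n_pcs)]
            row = [s.sample_id, s.status, s.sex, f"{s.age:.2f}", s.center]
            row += pcs + [s.cluster if s.cluster is not None else "NA"]
            fh.write("\t".join(row) + "\n")


def read_gene_list(path, name: str | None = None) -> GeneSet:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split()[0])
    return GeneSet(name or Path(path).stem, frozenset(genes))


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"GMT line {lineno}: expected name, description, genes")
            sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g)))
    return sets


def read_ped(path) -> list[Pedigree]:
    """Read a 6-column PED file (fam, id, father, mother, sex, phenotype)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"PED line {lineno}: expected 6 columns, got {len(fields)}")
            rows.append(fields[:6])

    seen = set()
    families: dict[str, list[PedigreeMember]] = {}
    for fam, iid, father, mother, sex, pheno in rows:
        if (fam, iid) in seen:
            raise ParseError(f"duplicate individual {iid} in family {fam}")
        seen.add((fam, iid))
        families.setdefault(fam, []).append(
            PedigreeMember(
                individual_id=iid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex={"1": "male", "2": "female"}.get(sex, "unknown"),
                affected={"2": "yes", "1": "no"}.get(pheno, "unknown"),
            )
        )
    return [Pedigree(fam, members) for fam, members in families.items()]


def write_ped(path, pedigrees: Sequence[Pedigree]) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    aff_code = {"yes": "2", "no": "1", "unknown": "0"}
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            sex_code[m.sex],
                            aff_code[m.affected],
                        ]
                    )
                    + "\n"
                )


def write_tsv(path, df: pd.DataFrame) -> None:
    """Write a results table with a commented pipeline-version header line."""
    with open(path, "w") as fh:
        fh.write(f"# {PIPELINE_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)
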