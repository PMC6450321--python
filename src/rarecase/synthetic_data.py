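"""Structured case-control exome cohort simulator with planted ground truth.

The real dementia sequencing cohorts this pipeline targets are
access-controlled, so every downstream stage is exercised against simulated
cohorts that carry the statistical structure the analysis assumes:

* ancestry substructure — background SNP frequencies diverge between
  subpopulations under a Balding-Nichols model (Beta-distributed subpopulation
  frequencies with variance Fst * p * (1 - p)); genotypes are Hardy-Weinberg
  within subpopulation,
* planted case-only deleterious variants with exact carrier counts,
  optionally restricted to one subpopulation and optionally riding a
  designated common haplotype over the surrounding SNP window,
* cryptic relatedness — duplicate / parent-offspring / full-sib /
  first-cousin pairs produced by gamete dropping from shared founders,
* confounded covariates — by default cases are younger (mean 76.4, SD 9.3
  years) than controls (mean 86.5, SD 4.5), reproducing the age-confounding
  direction of risk-score-selected sequencing cohorts.

Simulation is at the gamete (chromosome) level so haplotype-background
analyses have a defined truth.  Background SNPs are in linkage equilibrium
except on planted shared-haplotype windows, where carriers are placed on one
common haplotype in complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association_stats
from .core_io import (
    Annotation,
    GenotypeMatrix,
    Pedigree,
    SampleRecord,
    VariantRecord,
    write_phenotypes,
    write_tsv,
    write_vcf,
)

RELATIONSHIPS = ("duplicate", "parent_offspring", "full_sib", "first_cousin")


@dataclass
class PlantedVariantSpec:
    """One planted rare variant with exact case/control carrier counts."""

    gene: str
    impact: str = "MODERATE"
    consequence: str = "missense_variant"
    case_carriers: int = 0
    control_carriers: int = 0
    on_shared_haplotype: bool = False
    hap_freq_cases: float = 0.15
    hap_freq_controls: float = 0.14
    subpop: int | None = None
    homozygous: bool = False
    pop_af: float = 0.0002


@dataclass
class SimulationConfig:
    """Stated world of the simulated cohort.

    Defaults mirror the structured dementia case-control cohort the pipeline
    analyzes: 5617 cases and 4594 controls, a minor ancestry subcluster of
    ~6.8% of the sample, age/sex confounding between strata, and 2 ancestry
    principal components as covariates.
    """

    n_cases: int = 5617
    n_controls: int = 4594
    n_background_snps: int = 2000
    n_subpops: int = 2
    subpop_weights: tuple[float, ...] | None = None  # default: (0.932, 0.068)
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    planted: list[PlantedVariantSpec] = field(default_factory=list)
    related_pairs: list[tuple[str, int]] = field(default_factory=list)
    window_kb: float = 100.0
    snp_spacing_bp: int = 1000
    n_pcs: int = 2
    case_age: tuple[float, float] = (76.4, 9.3)
    control_age: tuple[float, float] = (86.5, 4.5)
    case_female_frac: float = 0.570
    control_female_frac: float = 0.590
    centers: tuple[str, ...] = ("CENTER1", "CENTER2", "CENTER3")
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cases, self.n_controls, self.n_background_snps) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must lie in (0, 1), got {self.fst}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.subpop_weights is None:
            if self.n_subpops == 2:
                self.subpop_weights = (0.932, 0.068)
            else:
                self.subpop_weights = tuple([1.0 / self.n_subpops] * self.n_subpops)
        if len(self.subpop_weights) != self.n_subpops:
            raise ValueError("one weight per subpopulation required")
        for rel, count in self.related_pairs:
            if rel not in RELATIONSHIPS:
                raise ValueError(f"unknown relationship {rel!r}")
            if count < 0:
                raise ValueError("relationship counts must be non-negative")


@dataclass
class SimulationTruth:
    """Ground truth recorded for every planted feature of the cohort."""

    planted: pd.DataFrame  # variant_key, gene, carriers, shared haplotype, window
    relationships: pd.DataFrame  # sample_a, sample_b, relationship
    ancestral_freqs: np.ndarray  # (n_background_snps,)
    subpop_freqs: np.ndarray  # (n_background_snps, n_subpops)
    subpop_labels: np.ndarray  # per-sample subpop index


@dataclass
class CohortSim:
    variants: list[VariantRecord]
    genotypes: GenotypeMatrix
    annotations: list[Annotation]
    samples: list[SampleRecord]
    truth: SimulationTruth
    config: SimulationConfig


def _meiosis(parent_gametes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid parent, free recombination across SNPs."""
    L = parent_gametes.shape[1]
    pick = rng.integers(0, 2, L)
    return parent_gametes[pick, np.arange(L)]


def _fresh_gametes(freqs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return (rng.random((n, freqs.size)) < freqs).astype(np.int8)


def simulate_cohort(config: SimulationConfig) -> CohortSim:
    """Simulate a structured case-control cohort with planted ground truth.

    Deterministic given ``config.seed``: the same config yields byte-identical
    output files.
    """
    rng = np.random.default_rng(config.seed)
    n_cases, n_controls = config.n_cases, config.n_controls
    n = n_cases + n_controls
    L = config.n_background_snps

    sample_ids = [f"CASE{i + 1:05d}" for i in range(n_cases)] + [
        f"CTRL{i + 1:05d}" for i in range(n_controls)
    ]
    is_case = np.array([True] * n_cases + [False] * n_controls)
    subpop = rng.choice(config.n_subpops, size=n, p=np.asarray(config.subpop_weights))

    # Balding-Nichols background frequencies
    p_anc = rng.uniform(*config.maf_range, size=L)
    F = config.fst
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    p_sub = np.column_stack([rng.beta(a, b) for _ in range(config.n_subpops)])

    positions = config.snp_spacing_bp * (np.arange(L) + 1)

    # gametes: (n, 2, L), Hardy-Weinberg within subpopulation
    gametes = np.empty((n, 2, L), dtype=np.int8)
    for s in range(config.n_subpops):
        members = np.where(subpop == s)[0]
        draws = rng.random((members.size, 2, L)) < p_sub[:, s]
        gametes[members] = draws.astype(np.int8)

    # planted variant positions, spaced evenly between background SNPs
    n_planted = len(config.planted)
    planted_pos = [
        int(config.snp_spacing_bp * ((k + 1) * L / (n_planted + 1)) + config.snp_spacing_bp // 2)
        for k in range(n_planted)
    ]

    # shared-haplotype backgrounds on the carrier windows (before relatedness,
    # so relatives inherit window haplotypes consistently)
    half_bp = config.window_kb * 1000.0 / 2.0
    shared_haps: list[tuple[np.ndarray, np.ndarray] | None] = []
    for spec, pos in zip(config.planted, planted_pos):
        if not spec.on_shared_haplotype:
            shared_haps.append(None)
            continue
        win = np.where(np.abs(positions - pos) <= half_bp)[0]
        H = rng.integers(0, 2, win.size).astype(np.int8)
        for stratum, freq in ((is_case, spec.hap_freq_cases), (~is_case, spec.hap_freq_controls)):
            members = np.where(stratum)[0]
            hit = rng.random((members.size, 2)) < freq
            for g in (0, 1):
                rows = members[hit[:, g]]
                gametes[np.ix_(rows, [g], win)] = H[None, None, :]
        shared_haps.append((win, H))

    # cryptic relatedness by gamete dropping from shared founders
    rel_rows = []
    used: set[int] = set()
    for rel, count in config.related_pairs:
        for _ in range(count):
            s = int(rng.integers(0, config.n_subpops))
            pool = [i for i in np.where(subpop == s)[0] if i not in used]
            if len(pool) < 2:
                raise ValueError(f"subpopulation {s} too small for requested related pairs")
            ia, ib = rng.choice(len(pool), 2, replace=False)
            A, B = pool[ia], pool[ib]
            used.update((A, B))
            freqs = p_sub[:, s]
            if rel == "duplicate":
                gametes[B] = gametes[A]
            elif rel == "parent_offspring":
                gametes[B, 0] = _meiosis(gametes[A], rng)
                gametes[B, 1] = _fresh_gametes(freqs, 1, rng)[0]
            elif rel == "full_sib":
                father = _fresh_gametes(freqs, 2, rng)
                mother = _fresh_gametes(freqs, 2, rng)
                for child in (A, B):
                    gametes[child, 0] = _meiosis(father, rng)
                    gametes[child, 1] = _meiosis(mother, rng)
            elif rel == "first_cousin":
                g1 = _fresh_gametes(freqs, 2, rng)
                g2 = _fresh_gametes(freqs, 2, rng)
                sibs = []
                for _ in range(2):
                    sibs.append(np.stack([_meiosis(g1, rng), _meiosis(g2, rng)]))
                for child, sib in zip((A, B), sibs):
                    spouse = _fresh_gametes(freqs, 2, rng)
                    gametes[child, 0] = _meiosis(sib, rng)
                    gametes[child, 1] = _meiosis(spouse, rng)
            rel_rows.append(
                {"sample_a": sample_ids[A], "sample_b": sample_ids[B], "relationship": rel}
            )

    # background variant records / annotations
    variants = [
        VariantRecord("1", int(pos), f"snp{j + 1}", "A", "G")
        for j, pos in enumerate(positions)
    ]
    annotations = [
        Annotation(
            v.key,
            f"BG{j // 50 + 1}",
            "intergenic_variant",
            "MODIFIER",
            {f"pop{s + 1}": round(float(p_sub[j, s]), 6) for s in range(config.n_subpops)},
        )
        for j, v in enumerate(variants)
    ]

    # planted variants: exact heterozygous (or homozygous) carrier counts
    planted_cols = np.zeros((n, n_planted), dtype=np.int8)
    planted_rows = []
    for k, (spec, pos) in enumerate(zip(config.planted, planted_pos)):
        if spec.case_carriers > n_cases or spec.control_carriers > n_controls:
            raise ValueError(f"planted carriers exceed stratum size for {spec.gene}")
        carrier_idx = []
        for want_case, n_want in ((True, spec.case_carriers), (False, spec.control_carriers)):
            eligible = np.where(
                (is_case == want_case)
                & ((subpop == spec.subpop) if spec.subpop is not None else True)
            )[0]
            if n_want > eligible.size:
                raise ValueError(
                    f"planted variant in {spec.gene}: {n_want} carriers requested but "
                    f"only {eligible.size} eligible samples"
                )
            picked = rng.choice(eligible, n_want, replace=False)
            carrier_idx.extend(int(i) for i in picked)
        planted_cols[carrier_idx, k] = 2 if spec.homozygous else 1
        # carriers ride the designated window haplotype on the carrier chromosome
        if shared_haps[k] is not None:
            win, H = shared_haps[k]
            for i in carrier_idx:
                gametes[i, 0, win] = H
        rec = VariantRecord("1", pos, f"planted{k + 1}", "C", "T")
        variants.append(rec)
        annotations.append(
            Annotation(rec.key, spec.gene, spec.consequence, spec.impact,
                       {"gnomad": spec.pop_af})
        )
        planted_rows.append(
            {
                "variant_key": rec.key,
                "gene": spec.gene,
                "impact": spec.impact,
                "case_carriers": spec.case_carriers,
                "control_carriers": spec.control_carriers,
                "carrier_ids": ",".join(sample_ids[i] for i in sorted(carrier_idx)),
                "shared_haplotype": (
                    "".join(str(x) for x in shared_haps[k][1]) if shared_haps[k] else ""
                ),
                "window_keys": (
                    ",".join(variants[j].key for j in shared_haps[k][0])
                    if shared_haps[k]
                    else ""
                ),
            }
        )

    dosage = np.concatenate([gametes.sum(axis=1, dtype=np.int8), planted_cols], axis=1)
    order = np.argsort([v.pos for v in variants], kind="stable")
    variants = [variants[j] for j in order]
    annotations = [annotations[j] for j in order]
    dosage = dosage[:, order]
    genotypes = GenotypeMatrix(sample_ids, [v.key for v in variants], dosage)

    # covariates, with the stated case/control confounding
    bg_cols = [v.key for v in variants if v.id.startswith("snp")]
    pcs = association_stats.compute_pcs(
        genotypes.subset_variants(bg_cols), k=config.n_pcs, seed=config.seed % (2**31)
    )
    samples = []
    for i, sid in enumerate(sample_ids):
        if is_case[i]:
            age = rng.normal(*config.case_age)
            female = rng.random() < config.case_female_frac
        else:
            age = rng.normal(*config.control_age)
            female = rng.random() < config.control_female_frac
        samples.append(
            SampleRecord(
                sid,
                "case" if is_case[i] else "control",
                sex="female" if female else "male",
                age=float(age),
                center=config.centers[int(rng.integers(0, len(config.centers)))],
                pcs=pcs[i],
                cluster=f"P{subpop[i] + 1}",
            )
        )

    truth = SimulationTruth(
        planted=pd.DataFrame(
            planted_rows,
            columns=[
                "variant_key", "gene", "impact", "case_carriers", "control_carriers",
                "carrier_ids", "shared_haplotype", "window_keys",
            ],
        ),
        relationships=pd.DataFrame(
            rel_rows, columns=["sample_a", "sample_b", "relationship"]
        ),
        ancestral_freqs=p_anc,
        subpop_freqs=p_sub,
        subpop_labels=subpop,
    )
    return CohortSim(variants, genotypes, annotations, samples, truth, config)


def write_cohort(outdir, sim: CohortSim) -> dict[str, Path]:
    """Emit VCF + annotation TSV + phenotype TSV + truth TSV for a simulation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "annotations": outdir / "annotations.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(paths["vcf"], sim.variants, sim.genotypes,
              extra_header=[f"##seed={sim.config.seed}"])
    pops = sorted({p for a in sim.annotations for p in a.pop_af})
    ann_df = pd.DataFrame(
        [
            {
                "variant_key": a.variant_key,
                "gene": a.gene,
                "consequence": a.consequence,
                "impact": a.impact,
                **{f"AF_{p}": a.pop_af.get(p, "") for p in pops},
            }
            for a in sim.annotations
        ]
    )
    with open(paths["annotations"], "w") as fh:
        fh.write(f"# seed={sim.config.seed}\n")
        ann_df.to_csv(fh, sep="\t", index=False)
    write_phenotypes(paths["phenotypes"], sim.samples)
    write_tsv(paths["truth"], sim.truth.planted)
    return paths


def simulate_pedigree_genotypes(
    pedigree: Pedigree,
    founder_freqs: np.ndarray,
    planted: str | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop genotypes through a pedigree with Mendelian transmission.

    Founders draw gametes from ``founder_freqs``; every non-founder receives
    one gamete from each parent (free recombination across sites, no
    mutation).  ``planted`` names a founder who is made heterozygous for an
    extra variant (key ``"1:<last_pos>:C:T"``) absent from all other founders,
    so descent of a planted allele can be traced.
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(founder_freqs, dtype=float)
    L = freqs.size
    members = {m.individual_id: m for m in pedigree.members}
    if planted is not None:
        if planted not in members:
            raise ValueError(f"planted founder {planted!r} not in pedigree")
        if members[planted].father_id is not None or members[planted].mother_id is not None:
            raise ValueError(f"planted individual {planted!r} is not a founder")

    n_cols = L + (1 if planted is not None else 0)
    gametes: dict[str, np.ndarray] = {}

    def resolve(iid: str) -> np.ndarray:
        if iid in gametes:
            return gametes[iid]
        m = members[iid]
        g = np.zeros((2, n_cols), dtype=np.int8)
        if m.father_id is None and m.mother_id is None:
            g[:, :L] = _fresh_gametes(freqs, 2, rng)
            if planted == iid:
                g[0, L] = 1
        elif m.father_id is not None and m.mother_id is not None:
            g[0] = _meiosis(resolve(m.father_id), rng)
            g[1] = _meiosis(resolve(m.mother_id), rng)
        else:
            raise ValueError(f"{iid} has exactly one known parent; need both or none")
        gametes[iid] = g
        return g

    ids = [m.individual_id for m in pedigree.members]
    for iid in ids:
        resolve(iid)
    keys = [f"1:{1000 * (j + 1)}:A:G" for j in range(L)]
    if planted is not None:
        keys.append(f"1:{1000 * (L + 1)}:C:T")
    dosage = np.stack([gametes[iid].sum(axis=0) for iid in ids])
    return GenotypeMatrix(ids, keys, dosage)
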