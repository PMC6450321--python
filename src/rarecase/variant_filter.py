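"""Impact classification, carrier counting and case-only variant filters.

The discovery strategy is non-statistical: a variant is a candidate when it is
carried by at least a threshold number of cases and by no (called) controls.
Four filtering schemes are provided, differing in the impact classes admitted,
the case-carrier threshold, an optional prior-evidence gene list, and an
optional requirement of several distinct qualifying variants per gene:

========================  =======================  ============  =========
scheme                    impacts                  min cases     extra
========================  =======================  ============  =========
candidate_gene            HIGH, MODERATE           4             gene list
genomewide_moderate_high  HIGH, MODERATE           10            —
multi_variant_gene        HIGH, MODERATE           5             >= 3 distinct
                                                                 variants/gene
genomewide_high           HIGH                     7             —
========================  =======================  ============  =========

"Observed in N participants" counts carrier individuals (dosage >= 1), not
alleles; missing control genotypes never count against "absent in controls".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING, Annotation, GeneSet, GenotypeMatrix, SampleRecord

logger = logging.getLogger(__name__)

#: Sequence-Ontology consequence -> impact class.  Configurable because
#: annotation-tool tables differ; this is the SnpEff/VEP consensus core.
DEFAULT_IMPACT_TABLE: dict[str, str] = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "frameshift_variant": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "missense_variant": "MODERATE",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "protein_altering_variant": "MODERATE",
    "synonymous_variant": "LOW",
}


def classify_impact(consequence: str, table: Mapping[str, str] | None = None) -> str:
    """Map a Sequence-Ontology consequence term to an impact class.

    Unrecognized terms fall through to MODIFIER with a logged warning rather
    than failing, so novel annotation vocabularies degrade gracefully.
    """
    table = DEFAULT_IMPACT_TABLE if table is None else table
    impact = table.get(consequence)
    if impact is None:
        logger.warning("unrecognized consequence term %r -> MODIFIER", consequence)
        return "MODIFIER"
    return impact


def load_impact_table(path) -> dict[str, str]:
    """Load a two-column (consequence, impact) TSV override of the default table."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["consequence", "impact"],
                     header=None, dtype=str)
    return dict(zip(df["consequence"], df["impact"]))


@dataclass(frozen=True)
class CarrierCount:
    """Case/control carrier and allele tallies for one variant."""

    variant_key: str
    n_case_carriers: int
    n_control_carriers: int
    case_alt_alleles: int
    control_alt_alleles: int
    n_case_called: int
    n_control_called: int

    def __post_init__(self):
        for name in (
            "n_case_carriers", "n_control_carriers", "case_alt_alleles",
            "control_alt_alleles", "n_case_called", "n_control_called",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative for {self.variant_key}")
        if self.n_case_carriers > self.n_case_called:
            raise ValueError(f"case carriers exceed called cases at {self.variant_key}")
        if self.n_control_carriers > self.n_control_called:
            raise ValueError(f"control carriers exceed called controls at {self.variant_key}")
        if self.case_alt_alleles > 2 * self.n_case_called:
            raise ValueError(f"case alt alleles exceed 2x called at {self.variant_key}")
        if self.control_alt_alleles > 2 * self.n_control_called:
            raise ValueError(f"control alt alleles exceed 2x called at {self.variant_key}")

    @property
    def all_missing(self) -> bool:
        return self.n_case_called + self.n_control_called == 0


def count_carriers(
    genotypes: GenotypeMatrix, samples: Sequence[SampleRecord]
) -> list[CarrierCount]:
    """Tally case/control carriers per variant; a carrier has dosage >= 1.

    Missing genotypes are excluded from the called denominators.
    """
    by_id = {s.sample_id: s for s in samples}
    if set(genotypes.sample_ids) != set(by_id):
        extra = set(genotypes.sample_ids) ^ set(by_id)
        raise ValueError(f"sample ids differ between matrix and records: {sorted(extra)[:5]}")
    is_case = np.array([by_id[s].status == "case" for s in genotypes.sample_ids])

    d = genotypes.dosage
    called = d != MISSING
    carrier = d >= 1
    dose = np.where(called, d, 0)

    out = []
    for j, key in enumerate(genotypes.variant_keys):
        out.append(
            CarrierCount(
                variant_key=key,
                n_case_carriers=int(carrier[is_case, j].sum()),
                n_control_carriers=int(carrier[~is_case, j].sum()),
                case_alt_alleles=int(dose[is_case, j].sum()),
                control_alt_alleles=int(dose[~is_case, j].sum()),
                n_case_called=int(called[is_case, j].sum()),
                n_control_called=int(called[~is_case, j].sum()),
            )
        )
        if out[-1].all_missing:
            logger.warning("all genotypes missing at %s", key)
    return out


SCHEME_NAMES = (
    "candidate_gene",
    "genomewide_moderate_high",
    "multi_variant_gene",
    "genomewide_high",
)


@dataclass
class FilterScheme:
    """One case-only filtering rule set."""

    name: str
    impacts: frozenset[str]
    min_case_carriers: int
    max_control_carriers: int = 0
    gene_list: GeneSet | None = None
    min_distinct_variants_per_gene: int | None = None
    max_pop_af: float | None = None

    def __post_init__(self):
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme {self.name!r}")
        self.impacts = frozenset(self.impacts)
        if not self.impacts <= {"HIGH", "MODERATE"}:
            raise ValueError(f"impacts must be within HIGH/MODERATE, got {self.impacts}")
        if self.min_case_carriers < 0 or self.max_control_carriers < 0:
            raise ValueError("thresholds must be non-negative")
        if self.name == "candidate_gene" and self.gene_list is None:
            raise ValueError("candidate_gene scheme requires a gene_list")


def candidate_gene_scheme(gene_list: GeneSet, **kw) -> FilterScheme:
    """Prior-evidence genes, HIGH+MODERATE, >= 4 cases, no controls."""
    return FilterScheme("candidate_gene", frozenset({"HIGH", "MODERATE"}), 4,
                        gene_list=gene_list, **kw)


def genomewide_moderate_high_scheme(**kw) -> FilterScheme:
    """Any gene, HIGH+MODERATE, >= 10 cases, no controls."""
    return FilterScheme("genomewide_moderate_high", frozenset({"HIGH", "MODERATE"}), 10, **kw)


def multi_variant_gene_scheme(**kw) -> FilterScheme:
    """Genes with >= 3 distinct variants, each >= 5 cases and no controls."""
    return FilterScheme("multi_variant_gene", frozenset({"HIGH", "MODERATE"}), 5,
                        min_distinct_variants_per_gene=3, **kw)


def genomewide_high_scheme(**kw) -> FilterScheme:
    """Any gene, HIGH only, >= 7 cases, no controls."""
    return FilterScheme("genomewide_high", frozenset({"HIGH"}), 7, **kw)


def apply_scheme(
    counts: Sequence[CarrierCount],
    annotations: Sequence[Annotation],
    scheme: FilterScheme,
) -> pd.DataFrame:
    """Apply one case-only filtering scheme.

    A (variant, gene) pair is retained iff its impact is admitted, its case
    carriers reach ``min_case_carriers``, its called control carriers do not
    exceed ``max_control_carriers``, its gene is in the optional gene list and
    no population frequency exceeds the optional ``max_pop_af``.  The
    multi-variant scheme additionally keeps only genes with at least
    ``min_distinct_variants_per_gene`` passing variants.

    Returns a DataFrame of retained rows with per-variant counts and the
    rationale (which criteria each passed).
    """
    count_by_key = {c.variant_key: c for c in counts}
    rows = []
    for ann in annotations:
        cc = count_by_key.get(ann.variant_key)
        if cc is None:
            continue
        impact_ok = ann.impact in scheme.impacts
        cases_ok = cc.n_case_carriers >= scheme.min_case_carriers
        controls_ok = cc.n_control_carriers <= scheme.max_control_carriers
        gene_ok = scheme.gene_list is None or ann.gene in scheme.gene_list
        af_ok = scheme.max_pop_af is None or all(
            af <= scheme.max_pop_af for af in ann.pop_af.values()
        )
        if impact_ok and cases_ok and controls_ok and gene_ok and af_ok:
            rows.append(
                {
                    "variant_key": ann.variant_key,
                    "gene": ann.gene,
                    "impact": ann.impact,
                    "consequence": ann.consequence,
                    "n_case_carriers": cc.n_case_carriers,
                    "n_control_carriers": cc.n_control_carriers,
                    "max_pop_af": max(ann.pop_af.values(), default=float("nan")),
                    "rationale": (
                        f"impact={ann.impact} in {sorted(scheme.impacts)}; "
                        f"cases {cc.n_case_carriers}>={scheme.min_case_carriers}; "
                        f"controls {cc.n_control_carriers}<={scheme.max_control_carriers}"
                    ),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "variant_key", "gene", "impact", "consequence", "n_case_carriers",
            "n_control_carriers", "max_pop_af", "rationale",
        ],
    )
    if scheme.min_distinct_variants_per_gene is not None and not df.empty:
        per_gene = df.groupby("gene")["variant_key"].nunique()
        keep = per_gene[per_gene >= scheme.min_distinct_variants_per_gene].index
        df = df[df["gene"].isin(keep)].reset_index(drop=True)
    return df


def flag_nonrare(
    annotations: Iterable[Annotation], af_threshold: float = 0.01
) -> pd.DataFrame:
    """Advisory flag: variant is common (AF > threshold) in some population.

    A candidate that is not rare in any reference population is unlikely to be
    a high-penetrance risk allele; the flag is advisory, never a hard filter.
    """
    rows = []
    for ann in annotations:
        offending = {p: af for p, af in ann.pop_af.items() if af > af_threshold}
        rows.append(
            {
                "variant_key": ann.variant_key,
                "gene": ann.gene,
                "flagged": bool(offending),
                "max_pop_af": max(ann.pop_af.values(), default=float("nan")),
                "populations_above": ",".join(sorted(offending)) or "",
            }
        )
    return pd.DataFrame(
        rows, columns=["variant_key", "gene", "flagged", "max_pop_af", "populations_above"]
    )
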