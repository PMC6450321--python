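"""Affected-relative sharing filters for pedigree sequencing data.

For a pedigree with two or more genotyped affected members (e.g. an
AD-affected cousin pair from a high-risk pedigree), a variant is a candidate
when every genotyped affected member carries it and it then survives a chain
of population-frequency, impact and gene-relevance filters.  The filters are
independent predicates, so the retained set does not depend on the order in
which they are applied; each step logs how many variants it removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_io import MISSING, Annotation, GeneSet, GenotypeMatrix, Pedigree


@dataclass
class FamilyFilterConfig:
    max_pop_af: float = 0.001
    impacts: frozenset[str] = frozenset({"HIGH", "MODERATE"})
    relevance_genes: GeneSet | None = None
    require_all_affected: bool = True
    missing_blocks: bool = True  # a missing genotype in an affected blocks sharing

    def __post_init__(self):
        if not 0.0 <= self.max_pop_af <= 1.0:
            raise ValueError(f"max_pop_af must lie in [0, 1], got {self.max_pop_af}")
        self.impacts = frozenset(self.impacts)


def shared_in_affected(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    missing_blocks: bool = True,
) -> list[str]:
    """Variants carried by every genotyped affected member of the pedigree.

    Affected members without genotype data are ignored.  By default a missing
    genotype in a genotyped affected blocks sharing (conservative); with
    ``missing_blocks=False`` missing calls are treated as non-blocking.
    """
    affected = [
        m.individual_id
        for m in pedigree.affected_members()
        if m.genotyped and m.individual_id in genotypes.sample_ids
    ]
    if len(affected) < 2:
        raise ValueError(
            f"family {pedigree.family_id}: need >= 2 genotyped affected members, "
            f"found {len(affected)}"
        )
    rows = genotypes.subset_samples(affected).dosage
    shared = []
    for j, key in enumerate(genotypes.variant_keys):
        col = rows[:, j]
        carries = col >= 1
        if missing_blocks:
            ok = carries.all()
        else:
            ok = (carries | (col == MISSING)).all() and carries.any()
        if ok:
            shared.append(key)
    return shared


@dataclass
class FamilyFilterReport:
    retained: list[str]
    removed: dict[str, int]  # filter step -> number removed
    rationale: dict[str, str] = field(default_factory=dict)  # dropped variant -> reason


_FILTER_STEPS = ("frequency", "impact", "relevance")


def apply_family_filters(
    shared_variants: Sequence[str],
    annotations: Sequence[Annotation],
    config: FamilyFilterConfig,
    order: Sequence[str] = _FILTER_STEPS,
) -> FamilyFilterReport:
    """Apply frequency, impact and gene-relevance filters to shared variants.

    * frequency: every listed population frequency must be <= ``max_pop_af``;
    * impact ("pathogenicity"): impact class must be admitted;
    * relevance: when ``relevance_genes`` is provided, the gene must be in it.

    Passing an explicitly empty relevance set is an error (distinct from "no
    relevance filter"); :class:`~rarecase.core_io.GeneSet` forbids empty sets
    for the same reason.
    """
    if set(order) != set(_FILTER_STEPS):
        raise ValueError(f"order must be a permutation of {_FILTER_STEPS}")
    if config.relevance_genes is not None and len(config.relevance_genes) == 0:
        raise ValueError("relevance gene set provided but empty")

    ann_by_key: dict[str, list[Annotation]] = {}
    for a in annotations:
        ann_by_key.setdefault(a.variant_key, []).append(a)
    uncovered = [v for v in shared_variants if v not in ann_by_key]
    if uncovered:
        raise ValueError(f"shared variants without annotation: {uncovered[:5]}")

    def passes_frequency(anns: list[Annotation]) -> bool:
        return any(
            all(af <= config.max_pop_af for af in a.pop_af.values()) for a in anns
        )

    def passes_impact(anns: list[Annotation]) -> bool:
        return any(a.impact in config.impacts for a in anns)

    def passes_relevance(anns: list[Annotation]) -> bool:
        if config.relevance_genes is None:
            return True
        return any(a.gene in config.relevance_genes for a in anns)

    predicates: Mapping[str, object] = {
        "frequency": passes_frequency,
        "impact": passes_impact,
        "relevance": passes_relevance,
    }

    retained = list(shared_variants)
    removed = {}
    rationale: dict[str, str] = {}
    for step in order:
        pred = predicates[step]
        keep, drop = [], []
        for v in retained:
            (keep if pred(ann_by_key[v]) else drop).append(v)
        for v in drop:
            rationale[v] = f"removed at {step} filter"
        removed[step] = len(drop)
        retained = keep
    return FamilyFilterReport(retained=retained, removed=removed, rationale=rationale)
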