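"""Haplotype-background and relatedness analysis around a focal rare variant.

When a rare allele is observed in several unrelated cases, two questions
decide its interpretation: do the carriers sit on one common SNP haplotype
(one ancestral mutation event), and are they cryptically related (inflated
counts)?  This module answers both:

* :func:`select_window` picks common SNPs within a kb window of the focal
  variant.
* :func:`em_haplotype_frequencies` runs the classical EM algorithm for
  haplotype frequencies from unphased multilocus genotypes (Excoffier-Slatkin
  style), marginalizing missing genotypes.
* :func:`shared_haplotype` intersects, across carriers, the haplotypes each
  carrier plausibly bears, and reports case/control frequencies of the shared
  background.
* :func:`ld_stats` gives two-locus D' and r^2 from the two-SNP EM fit.
* :func:`ibd_moments` is the standard method-of-moments IBD estimator from
  genome-wide IBS counts (PLINK-style, with small-sample frequency
  corrections), yielding pi-hat = P(IBD=1)/2 + P(IBD=2).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import MISSING, GenotypeMatrix, SampleRecord, VariantRecord

MAX_WINDOW_SNPS = 16
_MAX_EXPANSION = 1 << 20


# ---------------------------------------------------------------------------
# window selection
# ---------------------------------------------------------------------------


def select_window(
    variants: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    focal: str,
    window_kb: float = 100.0,
    min_maf: float = 0.05,
) -> list[str]:
    """Common SNPs within +/- window_kb/2 of the focal variant, by position.

    The focal variant itself is excluded.  Returns variant keys ordered by
    position; empty (with a warning) when no SNP qualifies.
    """
    by_key = {v.key: v for v in variants}
    if focal not in by_key:
        raise KeyError(f"focal variant {focal} not found")
    f = by_key[focal]
    half = window_kb * 1000.0 / 2.0
    mafs = dict(zip(genotypes.variant_keys, genotypes.mafs()))
    picked = [
        v
        for v in variants
        if v.key != focal
        and v.chrom == f.chrom
        and abs(v.pos - f.pos) <= half
        and v.key in mafs
        and np.isfinite(mafs[v.key])
        and mafs[v.key] >= min_maf
    ]
    picked.sort(key=lambda v: v.pos)
    if not picked:
        warnings.warn(f"no common SNPs within {window_kb} kb of {focal}")
    return [v.key for v in picked]


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeTable:
    """EM-estimated haplotype frequencies over a SNP window."""

    window: list[str]
    haplotypes: list[str]  # '0'/'1' allele strings, ALT == '1'
    freqs: np.ndarray
    loglik: float
    n_iter: int
    converged: bool = True
    ambiguous: bool = False
    logliks: list[float] = field(default_factory=list)  # per-iteration trace

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if (self.freqs < 0).any():
            raise ValueError("negative haplotype frequency")
        if self.freqs.size and abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {self.freqs.sum()}")
        L = len(self.window)
        if any(len(h) != L for h in self.haplotypes):
            raise ValueError("haplotype string length does not match window")

    def freq_of(self, hap: str) -> float:
        try:
            return float(self.freqs[self.haplotypes.index(hap)])
        except ValueError:
            return 0.0


_SITE_OPTIONS = {
    0: ((0, 0),),
    2: ((1, 1),),
    1: ((0, 1), (1, 0)),
    MISSING: ((0, 0), (0, 1), (1, 0), (1, 1)),
}


def _compatible_pairs(pattern: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """All ordered haplotype pairs (as bit codes) compatible with a genotype."""
    n = 1
    for g in pattern:
        n *= len(_SITE_OPTIONS[g])
        if n > _MAX_EXPANSION:
            raise ValueError("too many compatible phases; reduce window or missingness")
    h1 = [0]
    h2 = [0]
    for g in pattern:
        opts = _SITE_OPTIONS[g]
        h1 = [(x << 1) | a for a, _ in opts for x in h1]
        h2 = [(y << 1) | b for _, b in opts for y in h2]
    return np.array(h1, dtype=np.int64), np.array(h2, dtype=np.int64)


def _window_dosages(genotypes) -> np.ndarray:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.dosage
    return np.asarray(genotypes, dtype=np.int8)


def em_haplotype_frequencies(
    genotypes,
    tol: float = 1e-6,
    max_iter: int = 1000,
    init: np.ndarray | None = None,
    prune_floor: float = 1e-4,
    n_restarts: int = 1,
    seed: int = 0,
) -> HaplotypeTable:
    """EM haplotype-frequency estimation from unphased window genotypes.

    ``genotypes`` is a GenotypeMatrix or an (n, L) dosage array over an ordered
    SNP window (2 <= L <= 16).  The E-step distributes each individual's unit
    mass over all haplotype pairs compatible with its genotype, proportionally
    to the product of current frequencies (missing sites marginalized over both
    alleles); the M-step re-estimates frequencies from expected gamete counts.
    The observed-data log-likelihood is non-decreasing across iterations and is
    recorded per iteration in ``logliks``.

    Initialization is the linkage-equilibrium product of sample allele
    frequencies, plus ``n_restarts`` jittered restarts; the best final
    log-likelihood wins.  Haplotypes below ``prune_floor`` are pruned (and the
    rest renormalized) at the end.  A cohort that is heterozygous at every
    typed site leaves coupling/repulsion phase unidentified from the symmetric
    stationary point; that case is reported via ``ambiguous`` rather than
    broken arbitrarily.
    """
    window_keys = (
        list(genotypes.variant_keys)
        if isinstance(genotypes, GenotypeMatrix)
        else [f"snp{j}" for j in range(np.asarray(genotypes).shape[1])]
    )
    d = _window_dosages(genotypes)
    L = d.shape[1]
    if L < 2:
        raise ValueError("window must span at least 2 SNPs")
    if L > MAX_WINDOW_SNPS:
        raise ValueError(f"window of {L} SNPs exceeds the {MAX_WINDOW_SNPS}-SNP cap")

    keep = ~(d == MISSING).all(axis=1)
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} individuals with all-missing windows")
    d = d[keep]
    if d.shape[0] == 0:
        raise ValueError("no individuals with any called genotype in window")

    patterns, counts = np.unique(d, axis=0, return_counts=True)
    pair_idx = [_compatible_pairs(tuple(p)) for p in patterns]

    support = np.unique(np.concatenate([np.concatenate(p) for p in pair_idx]))
    code_to_idx = {c: i for i, c in enumerate(support)}
    S = support.size
    pair_sidx = [
        (
            np.array([code_to_idx[c] for c in h1]),
            np.array([code_to_idx[c] for c in h2]),
        )
        for h1, h2 in pair_idx
    ]
    n_total = counts.sum()

    # linkage-equilibrium start from sample allele frequencies
    called = d != MISSING
    with np.errstate(invalid="ignore"):
        p_alt = np.where(
            called.sum(axis=0) > 0,
            np.where(called, d, 0).sum(axis=0) / np.maximum(2 * called.sum(axis=0), 1),
            0.5,
        )
    p_alt = np.clip(p_alt, 1e-6, 1 - 1e-6)
    bits = ((support[:, None] >> np.arange(L - 1, -1, -1)) & 1).astype(float)
    f_le = np.exp((bits * np.log(p_alt) + (1 - bits) * np.log(1 - p_alt)).sum(axis=1))
    f_le = f_le / f_le.sum()

    rng = np.random.default_rng(seed)
    starts = [f_le if init is None else np.asarray(init, dtype=float) / np.sum(init)]
    for _ in range(n_restarts):
        jit = f_le * np.exp(rng.normal(0, 0.3, S))
        starts.append(jit / jit.sum())

    def run(f0):
        f = f0.copy()
        trace = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            acc = np.zeros(S)
            ll = 0.0
            for (i1, i2), n in zip(pair_sidx, counts):
                w = f[i1] * f[i2]
                s = w.sum()
                if s <= 0:
                    s = np.finfo(float).tiny
                ll += n * np.log(s)
                post = (n / s) * w
                np.add.at(acc, i1, post)
                np.add.at(acc, i2, post)
            trace.append(ll)
            f_new = acc / (2 * n_total)
            if np.max(np.abs(f_new - f)) < tol:
                f = f_new
                converged = True
                break
            f = f_new
        # final log-likelihood at the returned frequencies
        ll_final = 0.0
        for (i1, i2), n in zip(pair_sidx, counts):
            s = (f[i1] * f[i2]).sum()
            ll_final += n * np.log(max(s, np.finfo(float).tiny))
        return f, ll_final, trace, converged, it

    best = None
    for f0 in starts:
        res = run(f0)
        if best is None or res[1] > best[1]:
            best = res
    f, loglik, trace, converged, n_iter = best

    ambiguous = bool(
        np.all((patterns == 1) | (patterns == MISSING)) and np.any(patterns == 1)
    )

    mask = f >= prune_floor
    if not mask.any():
        mask = f == f.max()
    f_pruned = f[mask] / f[mask].sum()
    haps = ["".join(str((c >> (L - 1 - j)) & 1) for j in range(L)) for c in support[mask]]
    order = np.argsort(-f_pruned, kind="stable")
    return HaplotypeTable(
        window=window_keys,
        haplotypes=[haps[i] for i in order],
        freqs=f_pruned[order],
        loglik=float(loglik),
        n_iter=n_iter,
        converged=converged,
        ambiguous=ambiguous,
        logliks=trace,
    )


# ---------------------------------------------------------------------------
# shared haplotype among carriers
# ---------------------------------------------------------------------------


@dataclass
class SharedHaplotypeResult:
    haplotypes: list[str]  # background haplotypes common to all carriers
    case_freqs: dict[str, float]
    control_freqs: dict[str, float]
    per_carrier: dict[str, list[str]]  # carrier id -> plausible haplotypes


def _carrier_haplotypes(
    table: HaplotypeTable, window_dosage: np.ndarray, threshold: float
) -> list[str] | None:
    """Haplotypes the carrier bears with posterior mass >= threshold, or None
    when the window is entirely missing."""
    if np.all(window_dosage == MISSING):
        return None
    L = len(table.window)
    h1, h2 = _compatible_pairs(tuple(int(g) for g in window_dosage))
    fmap = {int(h, 2): f for h, f in zip(table.haplotypes, table.freqs)}
    w = np.array([fmap.get(a, 0.0) * fmap.get(b, 0.0) for a, b in zip(h1, h2)])
    total = w.sum()
    if total <= 0:
        return []
    post = w / total
    mass: dict[int, float] = {}
    for p, a, b in zip(post, h1, h2):
        members = {int(a), int(b)}
        for h in members:
            mass[h] = mass.get(h, 0.0) + p
    return [
        "".join(str((c >> (L - 1 - j)) & 1) for j in range(L))
        for c, m in mass.items()
        if m >= threshold
    ]


def shared_haplotype(
    table: HaplotypeTable,
    genotypes: GenotypeMatrix,
    carriers: Sequence[str],
    samples: Sequence[SampleRecord] | None = None,
    report_threshold: float = 0.5,
    **em_kwargs,
) -> SharedHaplotypeResult:
    """Background haplotypes shared by every carrier of a focal rare variant.

    For each carrier, haplotypes compatible with its window genotype and
    carrying posterior mass >= ``report_threshold`` under the EM fit are
    collected; the result is their intersection.  When ``samples`` is given,
    the frequency of each shared haplotype is re-estimated by EM separately in
    cases and in controls.
    """
    missing = [c for c in carriers if c not in genotypes.sample_ids]
    if missing:
        raise ValueError(f"carriers not in genotype matrix: {missing}")
    win = genotypes.subset_variants(table.window)

    per_carrier: dict[str, list[str]] = {}
    shared: set[str] | None = None
    for c in carriers:
        row = win.dosage[win.sample_ids.index(c)]
        haps = _carrier_haplotypes(table, row, report_threshold)
        if haps is None:
            warnings.warn(f"carrier {c} has an all-missing window; excluded")
            continue
        per_carrier[c] = haps
        shared = set(haps) if shared is None else shared & set(haps)
    shared_list = sorted(shared or set(), key=lambda h: -table.freq_of(h))

    case_freqs: dict[str, float] = {}
    control_freqs: dict[str, float] = {}
    if samples is not None and shared_list:
        by_id = {s.sample_id: s for s in samples}
        for label, out in (("case", case_freqs), ("control", control_freqs)):
            ids = [s for s in win.sample_ids if by_id[s].status == label]
            if not ids:
                continue
            sub = win.subset_samples(ids)
            t = em_haplotype_frequencies(sub, **em_kwargs)
            for h in shared_list:
                out[h] = t.freq_of(h)
    return SharedHaplotypeResult(shared_list, case_freqs, control_freqs, per_carrier)


# ---------------------------------------------------------------------------
# two-locus LD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LDStats:
    snp_pair: tuple[str, str]
    d_prime: float
    r2: float

    def __post_init__(self):
        if not (0 <= self.d_prime <= 1 + 1e-9 and 0 <= self.r2 <= 1 + 1e-9):
            raise ValueError("D' and r^2 must lie in [0, 1]")


def ld_stats(genotypes, keys: tuple[str, str] | None = None) -> LDStats:
    """D' and r^2 for a SNP pair from the two-locus EM haplotype fit.

    ALT is the counted allele at both loci:  D = p_AB - p_A p_B over ALT-ALT,
    D' = |D| / Dmax, r^2 = D^2 / (p_A q_A p_B q_B).  Both statistics are
    invariant to allele-label swaps.
    """
    d = _window_dosages(genotypes)
    if d.shape[1] != 2:
        raise ValueError("ld_stats expects exactly two SNPs")
    if keys is None:
        keys = (
            tuple(genotypes.variant_keys)
            if isinstance(genotypes, GenotypeMatrix)
            else ("snp0", "snp1")
        )
    called = d != MISSING
    for j in range(2):
        alt = np.where(called[:, j], d[:, j], 0).sum()
        tot = 2 * called[:, j].sum()
        if tot == 0 or alt == 0 or alt == tot:
            raise ValueError(f"SNP {keys[j]} is monomorphic")

    t = em_haplotype_frequencies(d, tol=1e-9)
    f = {h: fr for h, fr in zip(t.haplotypes, t.freqs)}
    p_ab = f.get("11", 0.0)
    p_a = f.get("10", 0.0) + p_ab
    p_b = f.get("01", 0.0) + p_ab
    D = p_ab - p_a * p_b
    if D >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if dmax <= 0 else min(abs(D) / dmax, 1.0)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = 0.0 if denom <= 0 else min(D * D / denom, 1.0)
    return LDStats(tuple(keys), d_prime, r2)


# ---------------------------------------------------------------------------
# method-of-moments IBD
# ---------------------------------------------------------------------------


@dataclass
class IBDEstimate:
    pair: tuple[str, str]
    p0: float
    p1: float
    p2: float
    n_snps: int = 0

    def __post_init__(self):
        for name in ("p0", "p1", "p2"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.p0 + self.p1 + self.p2 - 1.0) > 1e-6:
            raise ValueError("IBD probabilities must sum to 1")

    @property
    def pihat(self) -> float:
        return self.p1 / 2.0 + self.p2


def _expected_ibs_sums(dosage: np.ndarray, use: np.ndarray):
    """Summed P(IBS=j | IBD=i) over informative SNPs, with the unbiased
    small-sample products of allele frequencies (PLINK-style corrections)."""
    called = dosage != MISSING
    A = np.where(called, dosage, 0).sum(axis=0).astype(float)  # ALT allele count
    X = (2 * called.sum(axis=0)).astype(float)
    B = X - A

    poly = use & (A > 0) & (B > 0) & (X >= 4)
    A, B, X = A[poly], B[poly], X[poly]

    d3 = X * (X - 1) * (X - 2)
    d4 = d3 * (X - 3)
    p2q2 = A * (A - 1) * B * (B - 1) / d4
    p3q = A * (A - 1) * (A - 2) * B / d4
    pq3 = A * B * (B - 1) * (B - 2) / d4
    p4 = A * (A - 1) * (A - 2) * (A - 3) / d4
    q4 = B * (B - 1) * (B - 2) * (B - 3) / d4
    p2q = A * (A - 1) * B / d3
    pq2 = A * B * (B - 1) / d3
    p3 = A * (A - 1) * (A - 2) / d3
    q3 = B * (B - 1) * (B - 2) / d3

    E = {
        (0, 0): 2 * p2q2,
        (0, 1): 4 * p3q + 4 * pq3,
        (0, 2): p4 + q4 + 4 * p2q2,
        (1, 1): 2 * p2q + 2 * pq2,
        (1, 2): p3 + q3 + p2q + pq2,
    }
    return {k: float(v.sum()) for k, v in E.items()}, poly


def ibd_moments(
    genotypes: GenotypeMatrix,
    pair: tuple[str, str],
    min_informative: int = 100,
) -> IBDEstimate:
    """Method-of-moments P(IBD=0/1/2) and pi-hat for one sample pair.

    Observed genome-wide IBS0/1/2 counts over SNPs called in both pair members
    are equated with their expectations given IBD state — functions of sample
    allele frequencies with unbiased small-sample product corrections — and
    solved sequentially for P(IBD=0), P(IBD=1), P(IBD=2).  Negative solutions
    are truncated to zero and the triple renormalized; pi-hat = P1/2 + P2.
    """
    i = genotypes.sample_ids.index(pair[0])
    j = genotypes.sample_ids.index(pair[1])
    d = genotypes.dosage
    both = (d[i] != MISSING) & (d[j] != MISSING)

    E, poly = _expected_ibs_sums(d, both)
    gi, gj = d[i, poly].astype(int), d[j, poly].astype(int)
    n_snps = int(poly.sum())
    if n_snps < min_informative:
        raise ValueError(
            f"only {n_snps} informative SNPs for pair {pair}; need >= {min_informative}"
        )
    diff = np.abs(gi - gj)
    n_ibs0 = int((diff == 2).sum())
    n_ibs2 = int((diff == 0).sum())
    n_ibs1 = n_snps - n_ibs0 - n_ibs2

    p0 = n_ibs0 / E[(0, 0)] if E[(0, 0)] > 0 else 0.0
    p1 = (n_ibs1 - p0 * E[(0, 1)]) / E[(1, 1)] if E[(1, 1)] > 0 else 0.0
    p2 = (n_ibs2 - p0 * E[(0, 2)] - p1 * E[(1, 2)]) / n_snps

    p = np.clip([p0, p1, p2], 0.0, 1.0)
    p = p / p.sum() if p.sum() > 0 else np.array([1.0, 0.0, 0.0])
    return IBDEstimate((pair[0], pair[1]), float(p[0]), float(p[1]), float(p[2]), n_snps)


def mean_pairwise_pihat(
    genotypes: GenotypeMatrix,
    sample_set: Sequence[str],
    min_informative: int = 100,
) -> tuple[float, float]:
    """Mean and SD of pi-hat over all unordered pairs of ``sample_set``.

    This is the summary used to judge whether a group of rare-variant carriers
    is more closely related to each other than the cohort at large.
    """
    ids = list(sample_set)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples for pairwise IBD")
    pihats = [
        ibd_moments(genotypes, (a, b), min_informative=min_informative).pihat
        for a, b in itertools.combinations(ids, 2)
    ]
    arr = np.array(pihats)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
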