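"""Inferential statistics for the case-only pipeline.

Four ingredients:

* a pooled-variance two-proportion Z test (used for the ancestry-cluster
  carrier-enrichment comparison),
* the CMC (Combined and Multivariate Collapsing) burden procedure: rare
  qualifying variants in a gene set are collapsed into a per-sample burden
  which is tested by logistic regression with sex, age, sequencing center and
  ancestry principal-component covariates,
* hypergeometric (one-tailed Fisher) pathway over-representation with
  Benjamini-Hochberg FDR and fold enrichment,
* genotype-matrix principal components and subpopulation cluster assignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .core_io import MISSING, Annotation, GeneSet, GenotypeMatrix, SampleRecord


# ---------------------------------------------------------------------------
# two-proportion Z
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProportionTestResult:
    k1: int
    n1: int
    k2: int
    n2: int
    p1: float
    p2: float
    z: float
    p_two_sided: float
    degenerate: bool = False

    def __post_init__(self):
        if not (0 <= self.k1 <= self.n1 and 0 <= self.k2 <= self.n2):
            raise ValueError("carrier counts must satisfy 0 <= k <= n")
        if not 0 <= self.p_two_sided <= 1:
            raise ValueError("p-value outside [0, 1]")


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> ProportionTestResult:
    """Pooled-variance two-proportion Z test, two-sided, no continuity correction.

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (k1 + k2) / (n1 + n2).  A pooled proportion of exactly 0 or 1 has no
    variance; the result is then flagged degenerate with z = 0.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    p1, p2 = k1 / n1, k2 / n2
    phat = (k1 + k2) / (n1 + n2)
    if phat in (0.0, 1.0):
        return ProportionTestResult(k1, n1, k2, n2, p1, p2, 0.0, 1.0, degenerate=True)
    se = math.sqrt(phat * (1 - phat) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return ProportionTestResult(k1, n1, k2, n2, p1, p2, z, p)


def cluster_carrier_test(
    carrier_ids: Sequence[str],
    samples: Sequence[SampleRecord],
    cluster: str,
) -> ProportionTestResult:
    """Carrier enrichment among cases vs controls within one ancestry cluster."""
    carriers = set(carrier_ids)
    in_cluster = [s for s in samples if s.cluster == cluster]
    cases = [s for s in in_cluster if s.status == "case"]
    controls = [s for s in in_cluster if s.status == "control"]
    k1 = sum(s.sample_id in carriers for s in cases)
    k2 = sum(s.sample_id in carriers for s in controls)
    return two_proportion_z(k1, len(cases), k2, len(controls))


# ---------------------------------------------------------------------------
# CMC burden
# ---------------------------------------------------------------------------


def cmc_collapse(
    genotypes: GenotypeMatrix,
    annotations: Sequence[Annotation],
    gene_set: GeneSet,
    impacts: Sequence[str] = ("HIGH", "MODERATE"),
    maf_max: float = 0.01,
    mode: str = "count",
) -> tuple[np.ndarray, list[str]]:
    """Collapse qualifying rare variants into a per-sample burden.

    A variant qualifies when some annotation places it in ``gene_set`` with an
    admitted impact and its sample minor-allele frequency is <= ``maf_max``.
    ``mode="count"`` sums minor-allele dosages over qualifying variants (the
    default; one unit per allele); ``mode="indicator"`` is the classical CMC
    0/1 collapse.  Returns (burden aligned with ``genotypes.sample_ids``,
    qualifying variant keys).
    """
    if mode not in ("count", "indicator"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    impacts = frozenset(impacts)
    eligible = {
        a.variant_key
        for a in annotations
        if a.impact in impacts and a.gene in gene_set
    }
    afs = dict(zip(genotypes.variant_keys, genotypes.alt_freqs()))
    qualifying = [
        k
        for k in genotypes.variant_keys
        if k in eligible
        and np.isfinite(afs[k])
        and min(afs[k], 1 - afs[k]) <= maf_max
    ]
    if not qualifying:
        raise ValueError(
            f"no qualifying variants (impacts={sorted(impacts)}, "
            f"gene_set={gene_set.name!r}, maf_max={maf_max})"
        )
    sub = genotypes.subset_variants(qualifying)
    d = sub.dosage.astype(float)
    d[d == MISSING] = 0.0
    # count the minor allele: fold dosage at variants where ALT is the major allele
    for j, k in enumerate(qualifying):
        if afs[k] > 0.5:
            d[:, j] = 2.0 - d[:, j]
    burden = d.sum(axis=1)
    if mode == "indicator":
        burden = (burden > 0).astype(float)
    return burden, qualifying


@dataclass
class BurdenResult:
    beta: float
    se: float
    p: float
    n_carrier_variants_cases: int
    n_carrier_variants_controls: int
    model: str

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if not 0 <= self.p <= 1:
            raise ValueError("p-value outside [0, 1]")


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth bias-reduced logistic regression (Jeffreys-prior penalized MLE)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return beta, np.sqrt(np.diag(cov))


def _design_matrix(
    samples: Sequence[SampleRecord], n_pcs: int, covariates: Sequence[str]
) -> tuple[pd.DataFrame, str]:
    cols: dict[str, object] = {}
    if "sex" in covariates:
        cols["sex"] = [s.sex for s in samples]
    if "age" in covariates:
        cols["age"] = [s.age for s in samples]
    if "center" in covariates:
        cols["center"] = [s.center for s in samples]
    df = pd.DataFrame(cols)
    if not df.empty:
        df = pd.get_dummies(df, columns=[c for c in ("sex", "center") if c in df],
                            drop_first=True, dtype=float)
    if "pcs" in covariates and n_pcs > 0:
        for i in range(n_pcs):
            df[f"PC{i + 1}"] = [
                s.pcs[i] if i < s.pcs.size else 0.0 for s in samples
            ]
    # drop constant columns (e.g. a single sequencing center)
    df = df.loc[:, df.nunique() > 1] if not df.empty else df
    desc = ", ".join(df.columns) if not df.empty else "none"
    return df, desc


def burden_logistic(
    burden: np.ndarray,
    samples: Sequence[SampleRecord],
    n_pcs: int = 2,
    covariates: Sequence[str] = ("sex", "age", "center", "pcs"),
    collapse_mode: str = "count",
) -> BurdenResult:
    """Logistic regression of case status on the collapsed burden.

    Maximum-likelihood fit (IRLS) with a Wald test on the burden coefficient;
    on (quasi-)separation a Firth penalized fit is substituted and flagged in
    the model description.  Also reports the cumulative qualifying-allele
    counts among cases and controls.
    """
    burden = np.asarray(burden, dtype=float)
    if burden.std() == 0:
        raise ValueError("burden has no variation; nothing to test")
    y = np.array([1.0 if s.status == "case" else 0.0 for s in samples])
    if len(np.unique(y)) < 2:
        raise ValueError("both cases and controls are required")

    cov_df, cov_desc = _design_matrix(samples, n_pcs, covariates)
    X = pd.concat(
        [pd.Series(burden, name="burden"), cov_df.reset_index(drop=True)], axis=1
    )
    X = sm.add_constant(X, has_constant="add").astype(float)
    Xv = X.to_numpy()
    burden_idx = list(X.columns).index("burden")

    firth = False
    beta = se = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is detected and handled below
            fit = sm.Logit(y, Xv).fit(disp=0, maxiter=50, tol=1e-8)
        beta = fit.params[burden_idx]
        se = fit.bse[burden_idx]
        if not np.isfinite(se) or se > 1e3 or not fit.mle_retvals.get("converged", True):
            firth = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        firth = True
    if firth:
        params, bses = _firth_logistic(Xv, y)
        beta, se = params[burden_idx], bses[burden_idx]

    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    model = (
        f"logit(case) ~ burden ({collapse_mode}) + {cov_desc}"
        + (" [Firth penalized: separation]" if firth else "")
    )
    return BurdenResult(
        beta=float(beta),
        se=float(se),
        p=float(p),
        n_carrier_variants_cases=int(burden[y == 1].sum()),
        n_carrier_variants_controls=int(burden[y == 0].sum()),
        model=model,
    )


# ---------------------------------------------------------------------------
# pathway over-representation
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentRow:
    pathway: str
    n_annotated: int
    n_observed: int
    expected: float
    fold: float
    p_unadjusted: float
    fdr: float = float("nan")

    def __post_init__(self):
        if self.fold < 0:
            raise ValueError("fold enrichment must be non-negative")
        if not 0 <= self.p_unadjusted <= 1:
            raise ValueError("p-value outside [0, 1]")


#: Annotated human protein-coding genes; the default over-representation
#: universe (consistent with expected = 30 x 42 / 20996 = 0.06).
DEFAULT_UNIVERSE_SIZE = 20996


def enrichment_from_counts(
    pathway: str,
    network_size: int,
    n_annotated: int,
    n_observed: int,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> EnrichmentRow:
    """Hypergeometric over-representation for one pathway from raw counts.

    p = P(X >= n_observed) with population ``universe_size``, ``n_annotated``
    successes and ``network_size`` draws; expected = network_size *
    n_annotated / universe_size; fold = n_observed / expected.
    """
    if universe_size < network_size:
        raise ValueError("universe smaller than network")
    if n_observed > min(n_annotated, network_size):
        raise ValueError(
            f"{pathway}: observed {n_observed} exceeds min(annotated, network)"
        )
    expected = network_size * n_annotated / universe_size
    p = float(stats.hypergeom.sf(n_observed - 1, universe_size, n_annotated, network_size))
    fold = n_observed / expected if n_observed > 0 else 0.0
    return EnrichmentRow(pathway, n_annotated, n_observed, expected, fold, min(p, 1.0))


def fisher_enrichment(
    network: GeneSet,
    pathways: Sequence[GeneSet],
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> list[EnrichmentRow]:
    """Over-representation of a gene network in each pathway, with BH-FDR.

    ``n_annotated`` is the pathway size (genes annotated to it in the
    universe); ``n_observed`` the overlap with the network.
    """
    rows = [
        enrichment_from_counts(
            p.name, len(network), len(p), len(network.genes & p.genes), universe_size
        )
        for p in pathways
    ]
    if rows:
        fdrs = bh_fdr([r.p_unadjusted for r in rows])
        for r, q in zip(rows, fdrs):
            r.fdr = float(q)
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "n_annotated": r.n_annotated,
                "n_observed": r.n_observed,
                "expected": r.expected,
                "fold_enrichment": r.fold,
                "p_unadjusted": r.p_unadjusted,
                "fdr": r.fdr,
            }
            for r in rows
        ]
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# principal components & clustering
# ---------------------------------------------------------------------------


def compute_pcs(genotypes, k: int = 2, seed: int = 0) -> np.ndarray:
    """Top-k principal components of the column-standardized dosage matrix.

    Missing dosages are imputed to the per-SNP mean; monomorphic SNPs are
    dropped.  Returns an (n_samples, k) score matrix.
    """
    d = (
        genotypes.dosage if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    ).astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    std = d.std(axis=0)
    keep = std > 0
    if keep.sum() < k:
        raise ValueError(f"only {int(keep.sum())} non-monomorphic SNPs; need >= {k}")
    z = (d[:, keep] - mean[keep]) / std[keep]
    return PCA(n_components=k, svd_solver="randomized", random_state=seed).fit_transform(z)


def assign_cluster(
    pcs: np.ndarray,
    method: str = "kmeans",
    n_clusters: int = 2,
    seed: int = 0,
    gates: Mapping[str, Sequence[tuple[int, float, float]]] | None = None,
    labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Assign subpopulation labels from principal components.

    ``kmeans``: k-means with a fixed seed (labels "C0", "C1", ...).
    ``gates``: rectangular gates, each a list of (component, lo, hi) bounds;
    samples outside every gate get "ungated".  ``labels``: pass-through.
    """
    pcs = np.asarray(pcs, dtype=float)
    if method == "kmeans":
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(pcs)
        return np.array([f"C{c}" for c in km.labels_])
    if method == "gates":
        if not gates:
            raise ValueError("gates method requires gate definitions")
        out = np.array(["ungated"] * pcs.shape[0], dtype=object)
        for name, bounds in gates.items():
            inside = np.ones(pcs.shape[0], dtype=bool)
            for dim, lo, hi in bounds:
                inside &= (pcs[:, dim] >= lo) & (pcs[:, dim] <= hi)
            out[inside] = name
        return out.astype(str)
    if method == "labels":
        if labels is None or len(labels) != pcs.shape[0]:
            raise ValueError("labels method requires one label per sample")
        return np.asarray(labels, dtype=str)
    raise ValueError(f"unknown clustering method {method!r}")
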