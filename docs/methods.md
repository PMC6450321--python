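# Methods

This note documents the models, estimators and numerical choices behind
`rarecase`, and what the simulation-backed tests do and do not establish.

## Case-only filtering

A *carrier* is an individual with ALT dosage ≥ 1. "Observed in N
participants" counts carrier individuals, not alleles, so all thresholds are
carrier thresholds. Two conservative conventions apply throughout:

* half-calls (`./1`) and `./.` are missing; missing genotypes are excluded
  from called denominators;
* a control with a missing call never counts against "absent in controls" —
  a missing call is not evidence of presence.

The four schemes differ only in parameters (admitted impacts, minimum case
carriers, optional gene list, optional per-gene distinct-variant minimum,
optional population-frequency ceiling). The consequence→impact table is the
SnpEff/VEP consensus core and is overridable from a TSV, because annotation
pipelines differ in their exact vocabularies. The "not rare in some reference
population" flag (default threshold 0.01, the boundary of the burden
analysis's rare stratum) is advisory only: a case-only variant that is common
elsewhere is probably benign, but the decision is left to the analyst.

## EM haplotype frequencies

For a window of L ≤ 16 biallelic SNPs, the observed-data likelihood of
haplotype frequencies **f** is `Π_i Σ_{(h1,h2) ∈ C_i} f(h1) f(h2)`, where
`C_i` enumerates ordered haplotype pairs compatible with individual *i*'s
unphased genotype (missing sites marginalized over both alleles; per-genotype
expansion capped at 2^20 pairs, all-missing individuals excluded with a
warning). Individuals are grouped by genotype pattern so cost scales with the
number of distinct patterns, not cohort size.

* Initialization: linkage-equilibrium product of sample allele frequencies,
  plus one log-normal-jittered restart; best final log-likelihood wins.
* Convergence: max |Δf| < tol (default 1e-6), max 1000 iterations; a
  non-converged run is returned with `converged=False`. The log-likelihood
  trace is stored and is non-decreasing (an EM guarantee the tests assert).
* Pruning floor 1e-4 at the end (renormalized), matching common
  haplotype-viewer behavior; configurable.
* A cohort heterozygous at every typed site cannot distinguish coupling from
  repulsion; the symmetric stationary point is reported with
  `ambiguous=True` rather than broken arbitrarily.

Carrier-shared backgrounds: a carrier "plausibly bears" haplotype h when the
posterior probability that h is in its pair is ≥ 0.5 (configurable); the
shared background is the intersection over carriers, with stratum frequencies
re-estimated by EM separately in cases and controls. Two-locus D′ and r² come
from the same EM fit: `D = p_AB − p_A p_B`, `D′ = |D|/D_max`,
`r² = D²/(p_A q_A p_B q_B)`.

Under independent SNPs, the null sampling mean of this r² is ≈ 1/(n−1) for n
unphased diploids — the estimator is asymptotically the squared genotype
correlation, since phase carries no information at D = 0. (The familiar
1/(2n) null mean applies to phase-known gametes.) The tests check both the
closed form and agreement with the independent genotype-correlation route.

## Method-of-moments IBD

For each pair, genome-wide IBS0/1/2 counts over mutually called polymorphic
SNPs are equated to their expectations given IBD state. The per-SNP expected
IBS-given-IBD probabilities are polynomial in allele frequencies; each
monomial is replaced by its unbiased small-sample product (e.g.
`E[p²q²] = A(A−1)B(B−1)/(X(X−1)(X−2)(X−3))` with ALT count A, REF count B,
X = A + B over called genotypes), the PLINK-style correction for frequencies
estimated from the same sample (the pair included, for simplicity). The
sequential solution `P0 = N_IBS0/E00`, `P1 = (N_IBS1 − P0·E01)/E11`,
`P2 = (N_IBS2 − P0·E02 − P1·E12)/n` is truncated to [0, 1] and renormalized;
`π̂ = P1/2 + P2`.

Truncation makes per-pair π̂ non-negative, so the *population mean* over
unrelated pairs is biased upward by an amount that scales with the per-pair
sampling noise, i.e. like 1/√(panel size): ~0.04 at 2000 mixed-MAF SNPs,
~0.014 at 8000 common SNPs in our simulations (the untruncated mean is ~0.004
at 2000 SNPs). The unrelated-pair calibration test therefore uses an
8000-common-SNP panel — still far smaller than the ~10⁵+ markers of real
genome-wide panels, where the bias is negligible. Duplicate, full-sib and
first-cousin pairs are recovered at π̂ ≈ 1, 0.5 and 0.125 regardless.

## Cluster enrichment and principal components

PCs are computed from the column-standardized dosage matrix (missing imputed
to the SNP mean, monomorphic SNPs dropped) via randomized SVD with a fixed
seed. Clusters come from k-means (fixed seed), rectangular gates on
components, or supplied labels. The carrier-enrichment test inside a cluster
is the pooled two-proportion Z:
`z = (p1 − p2)/√(p̂(1−p̂)(1/n1 + 1/n2))`, two-sided normal p, no continuity
correction (this convention reproduces the published Z = 2.76 for 8/358 vs
0/337). A pooled proportion of exactly 0 or 1 has no variance; the result is
flagged degenerate with z = 0 instead of dividing by zero.

## CMC burden

Qualifying variants (admitted impact, gene in set, sample MAF ≤ cutoff —
default 0.01) are collapsed per sample. The default collapse is the
*count* of minor alleles (consistent with small per-unit log-odds in
published burden tables); the classical CMC 0/1 *indicator* is an option.
Case status is regressed on burden plus sex, linear age, one-hot sequencing
center (first level reference) and the first 2 ancestry PCs (configurable)
by maximum-likelihood logistic regression; on separation or non-convergence
a hand-rolled Firth (Jeffreys-penalized) fit is substituted and flagged in
the model description. Cumulative qualifying-allele counts are reported by
status.

## Pathway over-representation

One-tailed hypergeometric upper tail `P(X ≥ k)` with population = universe
size, successes = genes annotated to the pathway, draws = network size.
`expected = network × annotated / universe` and `fold = observed/expected`
satisfy `fold × expected = observed` exactly. The default universe is 20996
annotated human protein-coding genes, consistent with published expected
counts (30 × 42 / 20996 ≈ 0.060); it is configurable because annotation
universes differ between releases. BH-FDR is applied across pathways.

## Synthetic cohorts: what they emulate

Defaults state the target cohort: 5617 cases / 4594 controls; a minor
ancestry subcluster of weight 0.068 (≈ 358 cases + 337 controls); case ages
N(76.4, 9.3²) vs control ages N(86.5, 4.5²) and female fractions 0.570/0.590
(reproducing the age/sex confounding direction of risk-score-selected
cohorts); three sequencing centers; 2 ancestry PCs.

Choices where no value was externally fixed, made once: 2000 background SNPs
(enough for stable PCA and IBD at test scale), Fst 0.1 (separates
subpopulations on PC1 at that panel size; continental-scale divergence),
ancestral MAFs uniform on (0.05, 0.5), 1 kb SNP spacing.

Mechanics: ancestral frequencies are Uniform(maf_range); subpopulation
frequencies are Beta-distributed with variance `Fst·p(1−p)` (Balding–
Nichols); genotypes are gamete-level Hardy–Weinberg draws within
subpopulation. Planted variants receive *exactly* the requested heterozygous
(optionally homozygous) carrier counts. A planted shared background writes
one designated haplotype onto gametes at stratum-specific frequencies over
the surrounding window and forces it onto each carrier's carrier chromosome
(complete linkage within the window — realistic over tens of kb).
Relatedness pairs are produced by gamete dropping from fresh founders with
*free recombination across SNPs*, the right idealization for genome-wide
unlinked markers (window-level linkage is only needed, and only enforced, on
planted shared-haplotype windows). Pedigree gene-dropping uses the same
meiosis model with no mutation.

What green tests do **not** establish: the generator draws SNPs in linkage
equilibrium (no background LD), uses a flat frequency spectrum rather than a
realistic exome site-frequency spectrum, has no genotyping error or
batch/center genotype effects, and plants carriers independent of covariates.
Estimator calibration shown here therefore transfers to real cohorts only up
to those idealizations.

## Degenerate inputs and tie-breaking

* All-missing variant columns are counted (0 carriers, 0 called) and flagged.
* Monomorphic SNPs: error in `ld_stats`, dropped in PCA, skipped as
  uninformative in IBD.
* Haplotype tables are sorted by descending frequency with a stable sort;
  k-means and randomized SVD use fixed seeds, so all outputs are
  reproducible bit-for-bit given inputs and seeds.

## Limitations

No long-range/cohort-wide phasing, no pedigree-aware phasing, no
variance-component (SKAT-type) tests, no mixed models, no variant-calling QC,
and no in-silico pathogenicity scores — "pathogenicity" in the family filter
is operationalized as the impact class, with the frequency and relevance
filters carrying the rest. Window EM is exponential in window size and
capped at 16 SNPs.
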