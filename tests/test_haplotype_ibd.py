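"""EM haplotype estimation vs an exhaustive-likelihood oracle; LD; moment IBD."""

import itertools

import numpy as np
import pytest
from scipy import optimize

from rarecase import (
    GenotypeMatrix,
    PlantedVariantSpec,
    SimulationConfig,
    VariantRecord,
    em_haplotype_frequencies,
    ibd_moments,
    ld_stats,
    mean_pairwise_pihat,
    select_window,
    shared_haplotype,
    simulate_cohort,
)
from rarecase.core_io import MISSING


# ---------------------------------------------------------------------------
# window selection
# ---------------------------------------------------------------------------


def _gm_from_freqs(freqs, n, seed, positions=None, chrom="1"):
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs)
    dosage = rng.binomial(2, freqs, size=(n, freqs.size)).astype(np.int8)
    positions = positions or [1000 * (j + 1) for j in range(freqs.size)]
    variants = [VariantRecord(chrom, p, ".", "A", "G") for p in positions]
    gm = GenotypeMatrix([f"S{i}" for i in range(n)], [v.key for v in variants], dosage)
    return variants, gm


class TestSelectWindow:
    def test_interval_membership(self):
        variants, gm = _gm_from_freqs(
            [0.3] * 6, 100, 0, positions=[1000, 40_000, 50_000, 60_000, 99_000, 200_000]
        )
        focal = variants[2].key
        got = select_window(variants, gm, focal, window_kb=100, min_maf=0.05)
        # +/- 50 kb of pos 50_000, focal excluded
        assert got == [variants[0].key, variants[1].key, variants[3].key, variants[4].key]

    def test_min_maf_drops_rare_snp(self):
        variants, gm = _gm_from_freqs([0.3, 0.01, 0.3], 500, 1)
        got = select_window(variants, gm, variants[0].key, window_kb=100, min_maf=0.05)
        assert variants[1].key not in got

    def test_eight_snp_geometry(self):
        """An 8-SNP common-SNP scaffold spanning 12.9 kb is selected intact
        around a focal rare variant (synthetic fixture mirroring that geometry)."""
        snp_pos = [50_000 + d for d in (0, 1700, 3400, 5200, 7000, 8800, 11_100, 12_900)]
        freqs = [0.25] * 8 + [0.002]
        variants, gm = _gm_from_freqs(freqs, 2000, 2, positions=snp_pos + [56_000])
        focal = variants[-1].key
        got = select_window(variants, gm, focal, window_kb=30, min_maf=0.05)
        assert got == [v.key for v in variants[:-1]]
        span = variants[7].pos - variants[0].pos
        assert span == 12_900

    def test_empty_window_warns(self):
        variants, gm = _gm_from_freqs([0.3, 0.3], 50, 3, positions=[1000, 500_000])
        with pytest.warns(UserWarning, match="no common SNPs"):
            got = select_window(variants, gm, variants[0].key, window_kb=10)
        assert got == []


# ---------------------------------------------------------------------------
# EM vs exhaustive-likelihood oracle
# ---------------------------------------------------------------------------


def _oracle_mle(dosage, n_starts=12, seed=0):
    """Independent MLE of haplotype frequencies over the full 2^L simplex.

    Enumerates all ordered haplotype pairs compatible with each genotype by
    direct inspection, then maximizes the observed-data log-likelihood with a
    softmax-parametrized quasi-Newton search from many starts plus a
    Nelder-Mead polish.  Shares no code with the EM implementation.
    """
    dosage = np.asarray(dosage)
    n, L = dosage.shape
    haps = list(itertools.product((0, 1), repeat=L))
    H = len(haps)

    def compatible(g, h1, h2):
        for gj, a, b in zip(g, h1, h2):
            if gj != MISSING and a + b != gj:
                return False
        return True

    pair_lists = []
    for i in range(n):
        pairs = [
            (a, b)
            for a in range(H)
            for b in range(H)
            if compatible(dosage[i], haps[a], haps[b])
        ]
        pair_lists.append(np.array(pairs))

    def neg_loglik(theta):
        f = np.exp(theta - theta.max())
        f = f / f.sum()
        ll = 0.0
        for pairs in pair_lists:
            s = (f[pairs[:, 0]] * f[pairs[:, 1]]).sum()
            ll += np.log(max(s, 1e-300))
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        theta0 = np.log(rng.dirichlet(np.ones(H)) + 1e-9)
        res = optimize.minimize(neg_loglik, theta0, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
        res = optimize.minimize(neg_loglik, res.x, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-13,
                                         "maxiter": 20000, "maxfev": 20000})
        if best is None or res.fun < best.fun:
            best = res
    f = np.exp(best.x - best.x.max())
    f = f / f.sum()
    strings = ["".join(map(str, h)) for h in haps]
    return dict(zip(strings, f)), -best.fun


def _em_freq_dict(table):
    return {h: f for h, f in zip(table.haplotypes, table.freqs)}


class TestEMHaplotypes:
    def test_phase_certain_equals_gamete_counts(self):
        """All-homozygous cohort: phase is certain; frequencies are direct counts."""
        d = np.array([[0, 0]] * 6 + [[2, 2]] * 3 + [[2, 0]] * 1, dtype=np.int8)
        t = em_haplotype_frequencies(d)
        f = _em_freq_dict(t)
        assert f["00"] == pytest.approx(0.6)
        assert f["11"] == pytest.approx(0.3)
        assert f["10"] == pytest.approx(0.1)

    def test_two_snp_coupling_matches_oracle(self):
        """40 AABB + 40 aabb + 20 AaBb: the MLE is full coupling at 0.5/0.5."""
        d = np.array([[2, 2]] * 40 + [[0, 0]] * 40 + [[1, 1]] * 20, dtype=np.int8)
        t = em_haplotype_frequencies(d, tol=1e-9)
        oracle, oracle_ll = _oracle_mle(d[:20])  # same optimum shape, small n for speed
        f = _em_freq_dict(t)
        assert f["11"] == pytest.approx(0.5, abs=1e-4)
        assert f["00"] == pytest.approx(0.5, abs=1e-4)
        # frozen from the grid+polish oracle on the full data
        assert f.get("10", 0.0) < 1e-4 and f.get("01", 0.0) < 1e-4

    @pytest.mark.parametrize("seed,n,L", [(0, 60, 2), (1, 100, 3), (2, 40, 3), (3, 80, 3)])
    def test_em_matches_exhaustive_simplex_oracle(self, seed, n, L):
        rng = np.random.default_rng(seed)
        # draw genotypes from a random haplotype pool, with some missingness
        pool = rng.dirichlet(np.ones(2**L))
        haps = np.array(list(itertools.product((0, 1), repeat=L)))
        picks = rng.choice(2**L, size=(n, 2), p=pool)
        d = (haps[picks[:, 0]] + haps[picks[:, 1]]).astype(np.int8)
        d[rng.random(d.shape) < 0.03] = MISSING
        t = em_haplotype_frequencies(d, tol=1e-10, max_iter=5000, prune_floor=0.0)
        oracle_f, oracle_ll = _oracle_mle(d, seed=seed)
        assert t.loglik == pytest.approx(oracle_ll, abs=1e-6)
        f = _em_freq_dict(t)
        for h, fo in oracle_f.items():
            assert f.get(h, 0.0) == pytest.approx(fo, abs=1e-4)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, [0.3, 0.5, 0.2], size=(200, 3)).astype(np.int8)
        t = em_haplotype_frequencies(d, tol=1e-10)
        diffs = np.diff(t.logliks)
        assert (diffs >= -1e-9).all()

    def test_all_double_hets_flagged_ambiguous(self):
        d = np.array([[1, 1]] * 30, dtype=np.int8)
        t = em_haplotype_frequencies(d)
        assert t.ambiguous

    def test_window_too_small_or_large(self):
        with pytest.raises(ValueError, match="at least 2"):
            em_haplotype_frequencies(np.zeros((5, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="cap"):
            em_haplotype_frequencies(np.zeros((5, 17), dtype=np.int8))


# ---------------------------------------------------------------------------
# shared haplotype among carriers
# ---------------------------------------------------------------------------


def _shared_hap_sim(seed=31, case_carriers=10, fc=0.15, fo=0.14,
                    n_cases=400, n_controls=400):
    cfg = SimulationConfig(
        n_cases=n_cases, n_controls=n_controls, n_background_snps=100,
        n_subpops=1, window_kb=5.0,
        planted=[PlantedVariantSpec(
            gene="NOTCH3", case_carriers=case_carriers, on_shared_haplotype=True,
            hap_freq_cases=fc, hap_freq_controls=fo)],
        seed=seed,
    )
    return simulate_cohort(cfg)


class TestSharedHaplotype:
    def test_planted_background_in_intersection(self):
        sim = _shared_hap_sim()
        row = sim.truth.planted.iloc[0]
        window = row.window_keys.split(",")
        carriers = row.carrier_ids.split(",")
        table = em_haplotype_frequencies(sim.genotypes.subset_variants(window))
        res = shared_haplotype(table, sim.genotypes, carriers, sim.samples)
        assert row.shared_haplotype in res.haplotypes

    def test_two_backgrounds_empty_intersection(self):
        """Carriers placed on two different backgrounds share nothing."""
        rng = np.random.default_rng(5)
        L, n = 4, 200
        hapA = np.array([1, 1, 0, 0], dtype=np.int8)
        hapB = np.array([0, 0, 1, 1], dtype=np.int8)
        other = rng.binomial(1, 0.3, size=(2 * n, L)).astype(np.int8)
        g1 = other[:n].copy()
        d = g1 + other[n:]
        # carriers 0..4 on hapA, 5..9 on hapB (one chromosome forced)
        for i in range(5):
            d[i] = hapA + other[n + i]
        for i in range(5, 10):
            d[i] = hapB + other[n + i]
        gm = GenotypeMatrix([f"S{i}" for i in range(n)],
                            [f"1:{j}:A:G" for j in range(L)], d)
        table = em_haplotype_frequencies(gm)
        res = shared_haplotype(table, gm, [f"S{i}" for i in range(10)])
        assert res.haplotypes == []


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------


class TestLD:
    def test_complete_coupling(self):
        d = np.array([[2, 2]] * 30 + [[0, 0]] * 50 + [[1, 1]] * 20, dtype=np.int8)
        s = ld_stats(d)
        assert s.d_prime == pytest.approx(1.0, abs=1e-6)
        assert s.r2 == pytest.approx(1.0, abs=1e-6)

    def test_algebraic_case(self):
        """Only AB and ab haplotypes at 0.5 each: D = 0.25, r^2 = 1."""
        d = np.array([[2, 2]] * 25 + [[0, 0]] * 25 + [[1, 1]] * 50, dtype=np.int8)
        s = ld_stats(d)
        assert s.r2 == pytest.approx(1.0, abs=1e-6)
        assert s.d_prime == pytest.approx(1.0, abs=1e-6)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(11)
        d = rng.binomial(2, [0.4, 0.3], size=(300, 2)).astype(np.int8)
        s = ld_stats(d)
        for flip in ((0,), (1,), (0, 1)):
            d2 = d.copy()
            for j in flip:
                d2[:, j] = 2 - d2[:, j]
            s2 = ld_stats(d2)
            # invariance holds to EM convergence precision
            assert s2.d_prime == pytest.approx(s.d_prime, abs=1e-6)
            assert s2.r2 == pytest.approx(s.r2, abs=1e-6)

    def test_independent_snps_mean_r2(self):
        """Under independence r^2 ~ 0 over replicates.

        For unphased diploid data the EM r^2 is asymptotically the squared
        genotype correlation (phase carries no information at D = 0), whose
        sampling mean is ~1/(n-1); the dual genotype-correlation route is the
        independent oracle here.
        """
        rng = np.random.default_rng(13)
        n, reps = 100, 600
        em_vals, corr_vals = [], []
        for _ in range(reps):
            d = rng.binomial(2, [0.4, 0.4], size=(n, 2)).astype(np.int8)
            try:
                em_vals.append(ld_stats(d).r2)
            except ValueError:
                continue
            corr_vals.append(float(np.corrcoef(d[:, 0], d[:, 1])[0, 1] ** 2))
        assert np.mean(em_vals) == pytest.approx(np.mean(corr_vals), abs=0.002)
        assert np.mean(em_vals) == pytest.approx(1 / (n - 1), abs=0.004)

    def test_monomorphic_rejected(self):
        d = np.array([[0, 1]] * 20, dtype=np.int8)
        with pytest.raises(ValueError, match="monomorphic"):
            ld_stats(d)


# ---------------------------------------------------------------------------
# IBD moments
# ---------------------------------------------------------------------------


class TestIBD:
    def test_duplicates_pihat_near_one(self):
        cfg = SimulationConfig(n_cases=40, n_controls=40, n_background_snps=2000,
                               n_subpops=1, related_pairs=[("duplicate", 2)], seed=41)
        sim = simulate_cohort(cfg)
        for row in sim.truth.relationships.itertuples():
            est = ibd_moments(sim.genotypes, (row.sample_a, row.sample_b))
            assert est.pihat >= 0.95

    def test_too_few_snps_error_names_count(self):
        cfg = SimulationConfig(n_cases=10, n_controls=10, n_background_snps=50,
                               n_subpops=1, seed=42)
        sim = simulate_cohort(cfg)
        ids = sim.genotypes.sample_ids
        with pytest.raises(ValueError, match=r"\d+ informative"):
            ibd_moments(sim.genotypes, (ids[0], ids[1]), min_informative=100)

    def test_singleton_set_rejected(self, small_sim):
        with pytest.raises(ValueError, match="at least 2"):
            mean_pairwise_pihat(small_sim.genotypes, [small_sim.genotypes.sample_ids[0]])

    def test_cousin_pair_raises_group_mean(self):
        """A set mixing one cousin pair among unrelateds has strictly greater
        mean pairwise pi-hat than the unrelated-only set."""
        cfg = SimulationConfig(n_cases=40, n_controls=40, n_background_snps=3000,
                               n_subpops=1, maf_range=(0.2, 0.5),
                               related_pairs=[("first_cousin", 1)], seed=43)
        sim = simulate_cohort(cfg)
        a, b = sim.truth.relationships.iloc[0][["sample_a", "sample_b"]]
        unrelated = [s for s in sim.genotypes.sample_ids if s not in (a, b)][:8]
        m_unrel, _ = mean_pairwise_pihat(sim.genotypes, unrelated)
        m_mixed, _ = mean_pairwise_pihat(sim.genotypes, unrelated[:6] + [a, b])
        assert m_mixed > m_unrel
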