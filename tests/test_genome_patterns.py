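import numpy as np
import pytest
from scipy import stats

from evoregime.genome_patterns import (
    beta_clustering,
    classify_conditional_neutrality,
    enrichment_by_bin,
    fisher_screen,
    fst_decay,
    inversion_frequency,
    match_control_sites,
    standardized_correlation,
)


class TestEnrichment:
    def test_uniform_ratio_standardizes_to_one(self, rng):
        q = rng.uniform(0, 10, 3300)
        cls = np.tile([True, True, False], 1100)  # ratio 2 everywhere
        out = enrichment_by_bin(q, cls)
        assert np.allclose(out.loc[out["defined"], "standardized"], 1.0, atol=0.35)
        mean_std = out.loc[out["defined"], "standardized"].mean()
        assert mean_std == pytest.approx(1.0)

    def test_known_ratios_arithmetic(self):
        # build 11 bins with ratios (2,1,...,1)
        neglogq, is_a = [], []
        for b in range(11):
            n_a = 20 if b == 0 else 10
            neglogq += [b + 0.5] * (n_a + 10)
            is_a += [True] * n_a + [False] * 10
        out = enrichment_by_bin(np.array(neglogq), np.array(is_a))
        assert out.loc[0, "ratio"] == pytest.approx(2.0)
        assert out.loc[0, "standardized"] == pytest.approx(2.0 / (12 / 11))

    def test_empty_class_bin_flagged_and_excluded(self):
        neglogq = np.array([0.1] * 4 + [5.0] * 3)
        is_a = np.array([True, True, False, False, True, True, True])
        out = enrichment_by_bin(neglogq, is_a)
        assert not out.loc[10, "defined"]
        assert np.isnan(out.loc[10, "ratio"])

    def test_no_sites_errors(self):
        with pytest.raises(ValueError):
            enrichment_by_bin(np.array([]), np.array([], dtype=bool))


class TestClustering:
    def test_random_labels_fall_inside_band(self):
        rng = np.random.default_rng(1234)
        alpha = np.sort(rng.choice(2_000_000, 4000, replace=False))
        beta = rng.choice(alpha, 400, replace=False)
        out = beta_clustering(beta, alpha, window_lengths=(5000, 50_000), n_focal=300,
                              n_perm=60, seed=4)
        inside = (out["observed"] >= out["perm_lo"]) & (out["observed"] <= out["perm_hi"])
        assert inside.all()

    def test_contiguous_run_is_extreme(self):
        alpha = np.arange(1, 5001) * 100
        beta = alpha[1000:1050]  # one tight block
        out = beta_clustering(beta, alpha, window_lengths=(201,), n_focal=50, n_perm=40, seed=2)
        assert out.loc[0, "observed"] > out.loc[0, "perm_hi"]
        assert out.loc[0, "observed"] > 0.9

    def test_beta_must_be_subset(self):
        with pytest.raises(ValueError):
            beta_clustering(np.array([5]), np.array([1, 2, 3]))


class TestFstDecay:
    def test_constant_fst_everywhere(self):
        pos = np.arange(0, 4000, 10)
        fst = np.full(pos.size, 0.3)
        out = fst_decay(np.array([2000]), pos, fst)
        got = out.dropna(subset=["mean_fst"])
        assert np.allclose(got["mean_fst"], 0.3)

    def test_weighted_mean_in_window(self):
        out = fst_decay(
            np.array([0]), np.array([10, 20]), np.array([0.1, 0.5]), np.array([1.0, 3.0])
        )
        assert out.loc[0, "mean_fst"] == pytest.approx(0.4)

    def test_focal_site_excluded_from_first_window(self):
        out = fst_decay(np.array([10]), np.array([10, 20]), np.array([1.0, 0.2]))
        assert out.loc[0, "mean_fst"] == pytest.approx(0.2)


class TestInversionFrequency:
    def test_equal_frequencies_are_invariant_to_coverage(self):
        cov = np.array([10.0, 1000.0, 3.0])
        assert inversion_frequency(0.1 * cov, cov) == pytest.approx(0.1)

    def test_weighted_mean(self):
        assert inversion_frequency([2, 15], [10, 30]) == pytest.approx(0.425)

    def test_split_marker_invariance(self):
        whole = inversion_frequency([4, 6], [20, 30])
        split = inversion_frequency([2, 2, 6], [10, 10, 30])
        assert whole == pytest.approx(split)

    def test_no_coverage_undefined(self):
        assert np.isnan(inversion_frequency([0], [0]))


class TestConditionalNeutrality:
    def test_cn_in_cad(self):
        lab = classify_conditional_neutrality(0.45, 0.50, 0.50, 0.52, 0.9)
        assert lab[0] == "CN-in-cad"

    def test_large_ancestral_shift_fails(self):
        lab = classify_conditional_neutrality(0.30, 0.50, 0.50, 0.52, 0.9)
        assert lab[0] == "neither"

    def test_both_sides(self):
        lab = classify_conditional_neutrality(0.5, 0.5, 0.5, 0.5, 0.5)
        assert lab[0] == "both"


class TestStandardizedCorrelation:
    def test_identical_sets_give_exact_zero(self, rng):
        fa = rng.uniform(0, 1, 50)
        fb = fa + rng.normal(0, 0.05, 50)
        idx = np.arange(50)
        out = standardized_correlation(fa, fb, idx, idx)
        assert out["diff_cor"] == 0.0

    def test_constructed_anticorrelation(self):
        rng = np.random.default_rng(7)
        n = 200
        fa = rng.uniform(0, 1, n)
        fb = np.empty(n)
        fb[:100] = 1 - fa[:100]  # selected sites perfectly anti-correlated
        fb[100:] = rng.uniform(0, 1, 100)  # control independent
        out = standardized_correlation(fa, fb, np.arange(100), np.arange(100, 200))
        assert out["r_selected"] == pytest.approx(-1.0)
        assert abs(out["r_control"]) < 0.3
        assert out["diff_cor"] < -0.6

    def test_antisymmetric_under_label_swap(self, rng):
        fa, fb = rng.uniform(0, 1, 40), rng.uniform(0, 1, 40)
        s, c = np.arange(20), np.arange(20, 40)
        a = standardized_correlation(fa, fb, s, c)["diff_cor"]
        b = standardized_correlation(fa, fb, c, s)["diff_cor"]
        assert a == pytest.approx(-b)

    def test_minimum_set_sizes(self):
        with pytest.raises(ValueError):
            standardized_correlation([1, 2], [1, 2], np.array([0]), np.array([1]))

    def test_control_matching_tracks_pi_ini(self):
        rng = np.random.default_rng(8)
        pi = rng.uniform(0, 0.5, 2000)
        selected = np.flatnonzero(pi > 0.4)[:100]
        candidates = np.setdiff1d(np.arange(2000), selected)
        ctl = match_control_sites(candidates, selected, pi, rng)
        assert ctl.size > 0
        assert abs(pi[ctl].mean() - pi[selected].mean()) < 0.05


class TestFisherScreen:
    def test_identical_tables_p_one(self):
        out = fisher_screen([5], [10], [5], [10])
        assert out.loc[0, "p"] == 1.0

    def test_extreme_table_matches_hypergeometric_oracle(self):
        out = fisher_screen([20], [20], [0], [20])
        # two-sided p for (20,0 / 0,20): both one-sided tails equal 1/C(40,20)
        from math import comb

        expect = 2 / comb(40, 20)
        assert out.loc[0, "p"] == pytest.approx(expect)
        assert out.loc[0, "p"] == pytest.approx(
            stats.fisher_exact([[20, 0], [0, 20]])[1]
        )

    def test_zero_coverage_degenerate(self):
        out = fisher_screen([0], [0], [3], [10])
        assert out.loc[0, "p"] == 1.0

    def test_random_tables_match_scipy(self, rng):
        for _ in range(25):
            a, b = rng.integers(0, 15, 2)
            c, d = rng.integers(0, 15, 2)
            out = fisher_screen([a], [a + b], [c], [c + d])
            if a + b == 0 or c + d == 0:
                continue
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert out.loc[0, "p"] == pytest.approx(ref)
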