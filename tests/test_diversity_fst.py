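import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evoregime.diversity_fst import (
    anova_tukey,
    assign_region,
    corrected_site_pi,
    coverage_matched_fst,
    fst_nei,
    heterozygosities,
    pi_by_stratum,
    window_pi,
    x_autosome_contrast,
)


def _rows(snp_rows, n_invariant, cov=20):
    """Count rows: given SNP rows plus invariant A-monomorphic rows."""
    inv = np.zeros((n_invariant, 6), int)
    inv[:, 0] = cov
    return np.vstack([np.array(snp_rows).reshape(-1, 6), inv]) if snp_rows else inv


class TestWindowPi:
    def test_monomorphic_window_is_zero_and_valid(self):
        counts = _rows([], 10_000)
        pos = np.arange(1, 10_001)
        out = window_pi(["2L"] * 10_000, pos, counts)
        assert out.loc[0, "pi"] == 0.0
        assert out.loc[0, "valid"]

    def test_half_covered_window_invalid(self):
        counts = _rows([], 5000)
        pos = np.arange(1, 5001)
        out = window_pi(["2L"] * 5000, pos, counts)
        assert not out.loc[0, "valid"]
        assert out.loc[0, "fraction_covered"] == pytest.approx(0.5)

    def test_single_snp_against_direct_correction_oracle(self):
        # one 10/10 SNP at coverage 20 among 9,999 invariant sites
        counts = _rows([[10, 10, 0, 0, 0, 0]], 9999)
        pos = np.arange(1, 10_001)
        out = window_pi(["2L"] * 10_000, pos, counts, pool_size=140)
        c, n = 20, 140
        oracle = (1 - 0.5**2 - 0.5**2) * c / (c - 1) * n / (n - 1)
        assert out.loc[0, "pi"] == pytest.approx(oracle / 10_000)

    def test_min_count_silences_singletons(self):
        counts = _rows([[19, 1, 0, 0, 0, 0]], 0)
        out = window_pi(["2L"], [1], counts)
        assert out.loc[0, "pi"] == 0.0

    def test_coverage_bounds_exclude_sites(self):
        counts = _rows([[3, 0, 0, 0, 0, 0]], 0)  # 3x < min 4
        out = window_pi(["2L"], [1], counts)
        assert out.loc[0, "n_qual"] == 0
        assert np.isnan(out.loc[0, "pi"])

    def test_determinism(self):
        counts = _rows([[10, 10, 0, 0, 0, 0]], 50)
        pos = np.arange(1, 52)
        a = window_pi(["2L"] * 51, pos, counts)
        b = window_pi(["2L"] * 51, pos, counts)
        pd.testing.assert_frame_equal(a, b)

    def test_pool_size_validation(self):
        with pytest.raises(ValueError):
            corrected_site_pi(np.zeros((1, 6)), pool_size=1)


class TestPiByStratum:
    def test_identical_replicates_have_zero_se(self):
        mat = np.tile([[0.2]], (4, 5))
        out = pi_by_stratum(mat, np.array(["low"] * 4))
        assert out.loc[0, "se"] == 0.0

    def test_se_matches_hand_computation(self):
        mat = np.array([[0.1, 0.2, 0.3, 0.4, 0.5]])
        out = pi_by_stratum(mat, np.array(["high"]))
        assert out.loc[0, "mean_pi"] == pytest.approx(0.3)
        assert out.loc[0, "se"] == pytest.approx(np.sqrt(0.025) / np.sqrt(5))

    def test_empty_stratum_flagged_not_zero(self):
        mat = np.array([[0.1, 0.2]])
        out = pi_by_stratum(mat, np.array(["low"]))
        assert set(out["stratum"]) == {"low"}  # high simply absent, not zero


class TestAnovaTukey:
    def test_all_equal_values(self):
        f, p, *_ = anova_tukey({c: np.ones(5) for c in "abcd"})
        assert f == 0.0 and p == 1.0

    def test_degenerate_within_variance(self):
        f, p, *_ = anova_tukey({"a": np.zeros(5), "b": np.ones(5)})
        assert np.isinf(f) and p == 0.0

    def test_matches_scipy_and_closed_form(self, rng):
        groups = {c: rng.normal(i * 0.3, 1.0, 5) for i, c in enumerate("abcd")}
        f, p, d1, d2, tukey = anova_tukey(groups)
        ref = stats.f_oneway(*groups.values())
        assert (d1, d2) == (3, 16)
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        assert len(tukey) == 6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


class TestHeterozygositiesAndFst:
    @pytest.mark.parametrize(
        "freqs,hs,ht",
        [
            ((1, 0), 0.0, 0.5),
            ((0.3, 0.3, 0.3, 0.3, 0.3), 0.42, 0.42),
            ((0.2, 0.4), 0.40, 0.42),
        ],
    )
    def test_h_values(self, freqs, hs, ht):
        out_hs, out_ht = heterozygosities(np.array([freqs]))
        assert out_hs[0] == pytest.approx(hs)
        assert out_ht[0] == pytest.approx(ht)

    def test_full_fixation_gives_fst_one(self):
        hs, ht = heterozygosities(np.array([[1, 0, 1, 0, 1]]))
        assert fst_nei(hs, ht) == pytest.approx(1.0)
        assert ht[0] == pytest.approx(0.48)

    def test_identical_populations_give_zero(self):
        hs, ht = heterozygosities(np.tile([[0.25]], (10, 5)))
        assert fst_nei(hs, ht) == pytest.approx(0.0)

    def test_ratio_of_averages_arithmetic(self):
        assert fst_nei([0.40, 0.48], [0.42, 0.48]) == pytest.approx(1 - 0.88 / 0.90)

    def test_all_ht_zero_errors(self):
        with pytest.raises(ValueError):
            fst_nei([0.0], [0.0])


class TestCoverageMatchedFst:
    def test_equal_coverage_equals_plain_nei_exactly(self, rng):
        cov = np.full((50, 5), 30)
        tr = {}
        expected = {}
        for t in ("Salt", "Cad"):
            minor = rng.binomial(30, 0.4, size=(50, 5))
            tr[t] = (minor, cov)
            hs, ht = heterozygosities(minor / 30)
            expected[t] = fst_nei(hs, ht)
        out = coverage_matched_fst(tr, repeats=3, seed=0)
        for t in ("Salt", "Cad"):
            got = float(out.loc[out["treatment"] == t, "fst"].iloc[0])
            assert got == pytest.approx(expected[t], abs=1e-12)

    def test_rank_matching_bookkeeping_two_replicates(self, rng):
        # coverages (20,10) vs (10,5): matched depths are (10,5) for both
        tr = {
            "A": (np.array([[10, 5]]), np.array([[20, 10]])),
            "B": (np.array([[5, 2]]), np.array([[10, 5]])),
        }
        out = coverage_matched_fst(tr, repeats=2, seed=1)
        assert (out["n_sites"] == 1).all()

    def test_seed_determinism(self, rng):
        cov = rng.integers(5, 40, size=(30, 5))
        tr = {t: (rng.binomial(cov, 0.3), cov) for t in ("Salt", "Cad", "Temp", "Spatial")}
        a = coverage_matched_fst(tr, seed=3)
        b = coverage_matched_fst(tr, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestRegions:
    @pytest.mark.parametrize(
        "chrom,pos,expect",
        [
            ("2L", 5_000_000, "2L-left"),
            ("2L", 8_000_000, "none"),
            ("2R", 10_368_692, "2R-right"),
            ("3R", 17_055_560, "none"),
            ("X", 1, "X"),
        ],
    )
    def test_printed_boundaries(self, chrom, pos, expect):
        assert assign_region(chrom, pos) == expect

    def test_unknown_chrom(self):
        with pytest.raises(KeyError):
            assign_region("4", 100)


class TestXAutosomeContrast:
    def _frame(self, x_vals, auto_val=0.1):
        rows = []
        for t, x in zip("abcd", x_vals):
            rows.append({"treatment": t, "region": "X", "fst": x})
            for r in ("2L-left", "2R-right"):
                rows.append({"treatment": t, "region": r, "fst": auto_val})
        return pd.DataFrame(rows)

    def test_identical_values_give_t_zero(self):
        out = x_autosome_contrast(self._frame([0.1] * 4))
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_constant_difference_flagged_degenerate(self):
        out = x_autosome_contrast(self._frame([0.15] * 4))
        assert out["degenerate"]

    def test_matches_closed_form(self):
        diffs = np.array([0.01, 0.02, 0.02, 0.03])
        out = x_autosome_contrast(self._frame(0.1 + diffs))
        expect_t = diffs.mean() / (diffs.std(ddof=1) / 2)
        assert out["t"] == pytest.approx(expect_t)
        assert out["df"] == 3
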