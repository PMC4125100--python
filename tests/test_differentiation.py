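import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests

from evoregime.differentiation import (
    PairingScheme,
    by_adjust,
    call_beta,
    cmh_test,
    geometric_mean_p,
    pseudo_treatment_null,
    scan_pair,
    window_differentiation,
)


class TestPairingScheme:
    def test_rotational_reproduces_the_enumeration(self):
        s = PairingScheme.rotational(5, ancestors=False)
        assert s.pairings[0] == [(i, i) for i in range(5)]
        assert s.pairings[1] == [(i, (i + 1) % 5) for i in range(5)]
        s.validate(5, 5)

    def test_ancestor_pair_pinned_everywhere(self):
        s = PairingScheme.rotational(5, ancestors=True)
        for pairs in s.pairings:
            assert (0, 0) in pairs
        s.validate(6, 6)

    def test_duplicate_pairings_rejected(self):
        s = PairingScheme([[(0, 0)], [(0, 0)]])
        with pytest.raises(ValueError):
            s.validate(1, 1)


class TestCMH:
    def test_no_association_gives_p_one(self):
        tables = np.tile([[10, 10], [10, 10]], (6, 1, 1))
        stat, p = cmh_test(tables)
        assert stat == 0.0 and p == 1.0

    def test_matches_statsmodels_on_exhaustive_small_tables(self):
        cells = range(5)
        checked = 0
        for a, b, c, d in itertools.product(cells, repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            stat, p = cmh_test([[[a, b], [c, d]]])
            ref = StratifiedTable([np.array([[a, c], [b, d]])]).test_null_odds(correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-8), (a, b, c, d)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            checked += 1
        assert checked > 200

    def test_matches_statsmodels_on_multi_stratum_tables(self, rng):
        for _ in range(50):
            k = rng.integers(2, 7)
            tabs = rng.integers(1, 30, size=(k, 2, 2))
            stat, p = cmh_test(tabs)
            ref = StratifiedTable([t.T for t in tabs]).test_null_odds(correction=False)
            assert stat == pytest.approx(ref.statistic, rel=1e-9)

    def test_replicated_evidence_is_stronger(self):
        one = cmh_test([[[8, 2], [2, 8]]])[1]
        six = cmh_test(np.tile([[8, 2], [2, 8]], (6, 1, 1)))[1]
        assert six < one

    def test_degenerate_strata_dropped(self):
        with_junk = cmh_test([[[8, 2], [2, 8]], [[0, 0], [5, 5]]])
        clean = cmh_test([[[8, 2], [2, 8]]])
        assert with_junk == pytest.approx(clean)
        assert cmh_test([[[0, 0], [5, 5]]]) == (0.0, 1.0)


class TestBY:
    def test_single_p_unchanged(self):
        assert by_adjust([0.01])[0] == pytest.approx(0.01)

    def test_two_value_closed_form(self):
        # c(2) = 1.5: q = (min(0.001*2*1.5/1, 0.75), 0.5*2*1.5/2) = (0.003, 0.75)
        q = by_adjust([0.001, 0.5])
        assert q == pytest.approx([0.003, 0.75])

    def test_equal_p_closed_form(self):
        m = 7
        p0 = 0.01
        c_m = sum(1 / k for k in range(1, m + 1))
        q = by_adjust([p0] * m)
        assert q == pytest.approx([min(1, p0 * c_m)] * m)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(0, 1, 200)
        ours = by_adjust(p)
        theirs = multipletests(p, method="fdr_by")[1]
        assert ours == pytest.approx(theirs)

    def test_empty_input(self):
        assert by_adjust([]).size == 0

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 50)
        q = by_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestScan:
    def _groups(self, n_sites, f1, f2, cov=20, k=6, rng=None):
        rng = rng or np.random.default_rng(0)
        c = np.full((n_sites, k), cov)
        m1 = rng.binomial(cov, f1, size=(n_sites, k))
        m2 = rng.binomial(cov, f2, size=(n_sites, k))
        return m1, c, m2, c

    def test_identical_groups_give_p_one_and_no_beta(self):
        m = np.full((10, 6), 7)
        c = np.full((10, 6), 20)
        res = scan_pair(m, c, m, c)
        assert (res["p_comb"] == 1.0).all()
        assert (res["q"] == 1.0).all()
        assert not res["beta"].any()

    def test_replicate_symmetric_data_collapses_pairings(self):
        # identical counts in every replicate: all pairings equal, geometric
        # mean equals the common value
        m1 = np.tile([[6]], (5, 6))
        m2 = np.tile([[14]], (5, 6))
        c = np.full((5, 6), 20)
        res = scan_pair(m1, c, m2, c)
        pcols = res[[f"p_{i}" for i in range(1, 6)]].to_numpy()
        assert np.allclose(pcols, pcols[:, [0]])
        assert res["p_comb"].to_numpy() == pytest.approx(pcols[:, 0])

    def test_planted_differentiated_site_called_beta(self, rng):
        m1, c1, m2, c2 = self._groups(200, 0.5, 0.5, rng=rng)
        m1[0] = np.round(0.9 * 20)
        m2[0] = np.round(0.1 * 20)
        res = scan_pair(m1, c1, m2, c2)
        assert res.loc[0, "q"] < 1e-5
        assert res.loc[0, "beta"]
        assert res.loc[0, "dp"] == pytest.approx(0.8, abs=1e-9)

    def test_geometric_mean_floor_prevents_underflow(self):
        p = np.full((1, 5), 1e-330)
        assert geometric_mean_p(p)[0] > 0


class TestCallBeta:
    def _df(self, qvals, q_comb):
        d = {f"q_{i+1}": [qvals[i]] for i in range(5)}
        d["q"] = [q_comb]
        return pd.DataFrame(d)

    def test_per_pairing_requires_all_five(self):
        good = self._df([1e-6] * 5, 1e-6)
        mixed = self._df([1e-6] * 4 + [1e-4], 1e-6)
        assert call_beta(good, "per-pairing", 1e-5)[0]
        assert not call_beta(mixed, "per-pairing", 1e-5)[0]

    def test_combined_uses_combined_q(self):
        df = self._df([1.0] * 5, 1e-6)
        assert call_beta(df, "combined", 1e-5)[0]

    def test_unknown_rule_and_empty(self):
        with pytest.raises(ValueError):
            call_beta(self._df([1] * 5, 1), "bogus")
        assert call_beta(pd.DataFrame(), "combined").size == 0


class TestPseudoTreatmentNull:
    def test_copies_of_one_group_give_zero_beta(self, rng):
        cov = np.full((100, 5), 20)
        m = rng.binomial(20, 0.4, size=(100, 5))
        out = pseudo_treatment_null(m, cov, m.copy(), cov, n_combinations=4, seed=5)
        assert (out["n_beta"] == 0).all()

    def test_seed_reproducibility(self, rng):
        cov = np.full((50, 5), 20)
        mc = rng.binomial(20, 0.4, size=(50, 5))
        ms = rng.binomial(20, 0.4, size=(50, 5))
        a = pseudo_treatment_null(mc, cov, ms, cov, n_combinations=6, seed=9)
        b = pseudo_treatment_null(mc, cov, ms, cov, n_combinations=6, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_needs_two_populations_per_side(self):
        one = np.ones((5, 1), int)
        with pytest.raises(ValueError):
            pseudo_treatment_null(one, one, one, one)


class TestWindows:
    def test_single_site_window(self):
        res = pd.DataFrame({"q": [0.01], "dp": [0.2]})
        win = window_differentiation(res, ["2L"], [1])
        assert win.loc[0, ["start", "end"]].tolist() == [1, 5000]
        assert win.loc[0, "mean_neglogq"] == pytest.approx(2.0)

    def test_arithmetic_mean_of_neglogq(self):
        res = pd.DataFrame({"q": [0.1, 0.001], "dp": [0.0, 0.0]})
        win = window_differentiation(res, ["2L", "2L"], [10, 20])
        assert win.loc[0, "mean_neglogq"] == pytest.approx(2.0)

    def test_boundary_positions_split_windows(self):
        res = pd.DataFrame({"q": [0.1, 0.1], "dp": [0, 0]})
        win = window_differentiation(res, ["2L", "2L"], [5000, 5001])
        assert len(win) == 2
        assert win["n"].tolist() == [1, 1]
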