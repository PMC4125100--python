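import numpy as np
import pytest

from evoregime.simulate import (
    SimConfig,
    deterministic_step,
    deterministic_trajectory,
    effective_recombination,
    haplotypes_from_freq_ld,
    lkj_correlation,
    random_ld_structure,
    run_simulation,
    selection_recursion,
)


class TestLdStructure:
    def test_identity_correlation_means_zero_d(self, rng):
        p = np.full(5, 0.4)
        D, corr, _ = random_ld_structure(5, p, seed=1, eta=1e9)
        off = D[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 0.0, atol=0.02)

    def test_complete_coupling_two_loci(self):
        h = haplotypes_from_freq_ld(0.5, 0.5, 0.25)
        assert h == pytest.approx([0.5, 0.0, 0.0, 0.5])

    def test_independence(self):
        h = haplotypes_from_freq_ld(0.3, 0.6, 0.0)
        assert h == pytest.approx([0.18, 0.12, 0.42, 0.28])

    def test_worked_example(self):
        h = haplotypes_from_freq_ld(0.3, 0.6, 0.1)
        assert h == pytest.approx([0.28, 0.02, 0.32, 0.38])

    def test_infeasible_d_rejected(self):
        with pytest.raises(ValueError):
            haplotypes_from_freq_ld(0.1, 0.1, 0.5)

    def test_random_draws_always_feasible(self, rng):
        for i in range(200):
            p = rng.uniform(0.02, 0.98, 6)
            D, _, _ = random_ld_structure(6, p, seed=i)
            for a in range(6):
                for b in range(6):
                    if a != b:
                        h = haplotypes_from_freq_ld(p[a], p[b], D[a, b])
                        assert (h >= 0).all() and h.sum() == pytest.approx(1.0)

    def test_lkj_matrices_are_valid_correlations(self, rng):
        C = lkj_correlation(8, rng, eta=1.0, size=20)
        assert np.allclose(C, C.transpose(0, 2, 1))
        assert np.allclose(np.diagonal(C, axis1=1, axis2=2), 1.0)
        for m in C:
            assert np.linalg.eigvalsh(m).min() > -1e-9


class TestDeterministicRecursions:
    def test_standard_one_locus_recursion(self):
        # p' = p(1+s)/(1+ps) with fitness (1+s, 1)
        s = 0.1
        assert selection_recursion(0.5, 1 + s, 1.0) == pytest.approx(0.55 / 1.05)

    def test_neutral_invariance(self):
        assert deterministic_step(0.37, "temporal", 0.0, 3) == 0.37
        assert deterministic_step(0.37, "neutral", 0.5) == 0.37

    def test_spatial_symmetric_fixed_point(self):
        traj = deterministic_trajectory(0.5, "spatial", 0.08, 50)
        assert np.allclose(traj, 0.5)

    def test_spatial_attracts_toward_half(self):
        traj = deterministic_trajectory(0.3, "spatial", 0.2, 400)
        assert abs(traj[-1] - 0.5) < abs(0.3 - 0.5)
        assert traj[-1] > 0.3

    def test_constant_converges_monotonically(self):
        traj = deterministic_trajectory(0.2, "constant_A", 0.1, 200)
        assert (np.diff(traj) >= 0).all()
        assert (np.diff(traj[:50]) > 0).all()
        assert traj[-1] > 0.99

    def test_temporal_two_generation_cycle_is_nearly_neutral(self):
        traj = deterministic_trajectory(0.3, "temporal", 0.05, 2)
        assert traj[-1] == pytest.approx(0.3, abs=1e-3)


class TestStochasticEngine:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(regime="bogus")
        with pytest.raises(ValueError):
            SimConfig(N=447)
        with pytest.raises(ValueError):
            SimConfig(r_neutral=0.0)
        with pytest.raises(ValueError):
            SimConfig(s=-0.1)

    def test_seed_determinism(self):
        cfg = dict(regime="spatial", s=0.05, n_reps=20, N=100, generations=10)
        a = run_simulation(SimConfig(seed=5, **cfg))
        b = run_simulation(SimConfig(seed=5, **cfg))
        assert np.array_equal(a.freqs, b.freqs)

    def test_frequencies_stay_in_unit_interval(self):
        r = run_simulation(SimConfig(regime="constant_A", s=0.07, n_reps=30, N=50,
                                     generations=20, seed=2))
        assert (r.freqs >= 0).all() and (r.freqs <= 1).all()

    @pytest.mark.parametrize("N,t", [(50, 10), (448, 42)])
    def test_neutral_pi_decay_matches_closed_form(self, N, t):
        # E[2pq] decays by (1 - 1/2N) per generation under pure drift
        reps = 3000
        cfg = SimConfig(regime="neutral", s=0.0, n_selected=0, N=N, generations=t,
                        init_dist=("fixed", 0.5), ld_eta=None, n_reps=reps, seed=11)
        res = run_simulation(cfg)
        pi = res.neutral_pi()
        expect = 0.5 * (1 - 1 / (2 * N)) ** t
        se = pi.std(ddof=1) / np.sqrt(reps)
        assert abs(pi.mean() - expect) < 2 * se + 1e-4

    def test_selection_off_equals_neutral_regime(self):
        base = dict(n_reps=50, N=100, generations=15, n_selected=5)
        a = run_simulation(SimConfig(regime="temporal", s=0.0, seed=3, **base))
        b = run_simulation(SimConfig(regime="neutral", s=0.0, seed=3, **base))
        assert np.array_equal(a.freqs, b.freqs)

    def test_neutral_site_pi_nondecreasing_with_distance_under_constant_selection(self):
        # linked neutral diversity is reduced near selected targets
        pis = []
        for r in (0.001, 0.5):
            cfg = SimConfig(regime="constant_A", s=0.07, r_neutral=r, n_reps=400,
                            seed=9, N=448)
            pis.append(run_simulation(cfg).neutral_pi().mean())
        assert pis[0] < pis[1]

    def test_effective_recombination_harmonic_mean(self):
        r = effective_recombination(0.005, 40)
        assert r == pytest.approx(40 / (1 / 0.005 + 39 / 0.5))
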