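"""Community observables: diversity, similarity, distributions, dominance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dlv
from dlv import observables as obs
from dlv.workbench import make_fixture


positive_vectors = st.lists(
    st.floats(1e-6, 1e3, allow_nan=False, allow_infinity=False),
    min_size=2, max_size=20).map(np.array)


class TestEffectiveSize:
    def test_hand_example(self):
        assert obs.effective_size(np.array([0.6, 0.3, 0.1])) == pytest.approx(
            1 / 0.46)

    def test_single_dominant_limit(self):
        x = np.array([1.0] + [1e-12] * 9)
        assert obs.effective_size(x) == pytest.approx(1.0, abs=1e-8)

    @settings(max_examples=50, deadline=None)
    @given(x=positive_vectors)
    def test_simpson_bounds(self, x):
        s = obs.effective_size(x)
        assert 1.0 - 1e-9 <= s <= x.size + 1e-9

    def test_uniform_gives_S(self):
        assert obs.effective_size(np.full(7, 0.3)) == pytest.approx(7.0)


class TestDominantComponent:
    def test_hand_example_top_two(self):
        members = obs.dominant_component(np.array([0.6, 0.3, 0.1]))
        assert set(members) == {0, 1}

    def test_uniform_includes_all(self):
        assert len(obs.dominant_component(np.ones(6))) == 6

    def test_single_winner(self):
        x = np.array([1e-8, 1.0, 1e-8, 1e-8])
        assert list(obs.dominant_component(x)) == [1]

    def test_ties_break_by_lower_index(self):
        x = np.array([0.3, 0.5, 0.3, 0.01])
        members = obs.dominant_component(x)
        assert 1 in members and (0 in members) >= (2 in members)


class TestBrayCurtis:
    def test_identical_is_one(self):
        x = np.array([0.2, 3.0, 1e-5])
        assert obs.bray_curtis(x, x) == pytest.approx(1.0, abs=1e-15)

    def test_disjoint_is_zero(self):
        assert obs.bray_curtis(np.array([1.0, 1e-12]),
                               np.array([1e-12, 1.0])) < 1e-10

    def test_hand_example(self):
        assert obs.bray_curtis(np.array([2.0, 1.0]),
                               np.array([1.0, 1.0])) == pytest.approx(0.8)

    @settings(max_examples=50, deadline=None)
    @given(x=positive_vectors)
    def test_symmetry_and_bounds(self, x):
        rng = np.random.default_rng(0)
        y = x * rng.uniform(0.1, 10.0, x.size)
        a, b = obs.bray_curtis(x, y), obs.bray_curtis(y, x)
        assert a == pytest.approx(b, rel=1e-12)
        assert 0.0 <= a <= 1.0 + 1e-12

    def test_matches_printed_weighted_form(self):
        # w_i min/mean form evaluated literally equals the reduced form
        rng = np.random.default_rng(5)
        x, y = rng.uniform(0.01, 2.0, 30), rng.uniform(0.01, 2.0, 30)
        w = (x + y) / (x + y).sum()
        literal = np.sum(w * np.minimum(x, y) / ((x + y) / 2))
        assert obs.bray_curtis(x, y) == pytest.approx(literal, rel=1e-12)


class TestClosenessToEquilibrium:
    def test_single_species_dominant_set(self):
        # an isolated dominant species relaxes to carrying capacity 1;
        # BC(0.5, 1) = 2 * 0.5 / 1.5 = 2/3
        p = dlv.EcologicalParams(S=3, mu=0.5, sigma=0.3, lam=1e-8)
        M = dlv.sample_interactions(p, 0)
        x = np.array([[0.5], [1e-9], [1e-9]])
        traj = dlv.Trajectory(times=np.array([0.0]), x=x, params=p,
                              matrix_seed=0, x0_seed=0,
                              settings=dlv.IntegrationSettings())
        res = obs.closeness_to_equilibrium(traj, M, 0.0)
        assert res.converged
        assert res.similarity == pytest.approx(2 / 3, abs=1e-3)

    def test_chaotic_run_visits_high_and_degraded_similarity(self,
                                                            small_chaotic):
        traj, M = small_chaotic
        sims = obs.closeness_series(traj, M, traj.times[::100])
        sims = sims[np.isfinite(sims)]
        assert sims.max() > 0.9       # approaches few-species equilibria
        assert sims.min() < 0.75      # and is subverted by invaders

    def test_time_out_of_range_rejected(self, small_chaotic):
        traj, M = small_chaotic
        with pytest.raises(ValueError):
            obs.closeness_to_equilibrium(traj, M, traj.times[-1] + 100.0)


class TestCollectiveCorrelation:
    def test_small_snapshot_matches_double_loop(self):
        p = dlv.EcologicalParams(S=3, mu=0.5, sigma=0.3, lam=1e-8)
        M = dlv.sample_interactions(p, 2)
        x = np.array([[0.5], [0.2], [0.3]])
        traj = dlv.Trajectory(times=np.array([0.0]), x=x, params=p,
                              matrix_seed=2, x0_seed=0,
                              settings=dlv.IntegrationSettings())
        rho = obs.collective_correlation(traj, M)
        pvec = x[:, 0] / x.sum()
        z = M.z
        oracle = -sum(z[i, j] * pvec[i] * pvec[j]
                      for i in range(3) for j in range(3) if i != j)
        assert rho == pytest.approx(oracle, abs=1e-14)

    def test_sigma_zero_rejected(self):
        p = dlv.EcologicalParams(S=4, mu=0.5, sigma=0.0, lam=1e-8)
        M = dlv.sample_interactions(p, 0)
        traj = dlv.Trajectory(times=np.array([0.0]), x=np.ones((4, 1)),
                              params=p, matrix_seed=0, x0_seed=0,
                              settings=dlv.IntegrationSettings())
        with pytest.raises(ValueError):
            obs.collective_correlation(traj, M)


class TestTotalAbundanceRelation:
    def test_mu_one_zero_critical_rho(self):
        assert obs.critical_rho(1.0, 0.3, 9.0) == 0.0

    def test_nonpositive_denominator_flagged(self):
        with pytest.raises(ValueError):
            obs.predicted_X_bar(0.5, 0.3, 9.0, 10.0)

    def test_chaotic_phase_exceeds_one_over_mu(self, small_chaotic):
        traj, M = small_chaotic
        s = dlv.summarize(traj, M)
        assert s.rho_bar >= s.rho_c
        xpred = obs.predicted_X_bar(0.5, 0.3, s.Seff_bar, s.rho_bar)
        assert xpred > 1 / 0.5


class TestDistributions:
    def test_normalizations(self, small_chaotic):
        traj, _ = small_chaotic
        dist = obs.afd_sad(traj)
        np.testing.assert_allclose(dist.afd.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(dist.sad.sum(axis=0), traj.S)

    @pytest.mark.parametrize("nu", [1.1, 1.3, 1.5])
    def test_fitter_recovers_known_exponents(self, nu):
        samples = make_fixture("known_powerlaw_samples", seed=8, nu=nu,
                               n=400_000)
        edges = np.logspace(np.log10(1e-9), 1, 121)
        h, _ = np.histogram(samples, bins=edges)
        afd = (h / h.sum())[None, :]
        dist = obs.AbundanceDistributions(
            edges=edges, afd=afd, mean_afd=afd[0], sd_afd=np.zeros_like(afd[0]),
            snapshot_times=np.array([0.0]), sad=afd.T)
        fit = obs.fit_power_law(dist, window=(1e-6, 1e-2))
        assert abs(fit.nu - nu) < 0.05
        assert abs(obs.fit_power_law_mle(samples, (1e-6, 1e-2)) - nu) < 0.05

    def test_empty_window_rejected(self, small_chaotic):
        traj, _ = small_chaotic
        dist = obs.afd_sad(traj)
        with pytest.raises(ValueError):
            obs.fit_power_law(dist, window=(20.0, 50.0))


class TestACF:
    def test_pure_exponential_self_consistency(self):
        t = np.arange(0, 200.0, 1.0)
        tau = obs.fit_timescale(t, np.exp(-t / 20.0))
        assert tau == pytest.approx(20.0, rel=0.01)

    def test_ou_oracle(self):
        eta = make_fixture("ou_series", seed=4, tau=5.0, dt=0.05, T=10_000.0)
        phi = obs.acf(eta, max_lag=2000)
        lags = np.arange(phi.size) * 0.05
        assert obs.fit_timescale(lags, phi) == pytest.approx(5.0, rel=0.10)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            obs.acf(np.ones(100))

    def test_vector_acf_weights_by_variance(self):
        rng = np.random.default_rng(0)
        quiet = np.full(500, 5.0) + 1e-6 * rng.standard_normal(500)
        loud = np.sin(np.arange(500) * 0.1) * 10
        phi = obs.vector_acf(np.vstack([quiet, loud]))
        # the loud oscillator dominates: ACF oscillates rather than spikes
        assert phi[0] == pytest.approx(1.0)
        assert phi[31] < -0.5  # half-period of the sine


class TestDominance:
    def test_counting_identity(self, small_chaotic):
        traj, M = small_chaotic
        report = obs.dominance_stats(traj, M, min_turnovers=10)
        seff_bar = obs.effective_size_series(traj).mean()
        assert report.fraction.sum() == pytest.approx(
            report.mean_dominant_size, rel=1e-12)
        assert abs(report.mean_dominant_size - seff_bar) < 0.6

    def test_median_bias_is_one(self, small_chaotic):
        traj, M = small_chaotic
        report = obs.dominance_stats(traj, M, min_turnovers=10)
        assert np.median(report.bias) == pytest.approx(1.0)

    def test_bias_correlates_with_net_interaction_bias(self, reference_traj,
                                                       reference_matrix):
        # lower net competition (smaller z_i) -> more often dominant, as
        # implied by the mean selection coefficient -sigma*z_i/S
        from scipy.stats import spearmanr
        report = obs.dominance_stats(reference_traj, reference_matrix)
        r, _ = spearmanr(report.bias, report.z_bias)
        assert r < -0.2

    def test_doubling_S_squeezes_dominance_time(self):
        # doubling S halves the mean dominance fraction (the counting
        # identity sum_i fraction_i = Seff_bar with Seff nearly constant)
        # and pushes the median down; the median itself converges to the
        # 1/S law only on much longer horizons
        stats = {}
        for S in (200, 400):
            p = dlv.EcologicalParams(S=S, mu=0.5, sigma=0.3, lam=1e-8)
            M = dlv.sample_interactions(p, 21)
            s = dlv.IntegrationSettings(t_burn=500.0, t_run=6000.0, seed_x0=5)
            traj = dlv.integrate(M, dlv.initial_condition(p, s), s)
            rep = obs.dominance_stats(traj, M, min_turnovers=10)
            stats[S] = (rep.fraction.mean(), np.median(rep.fraction))
        assert stats[400][0] / stats[200][0] == pytest.approx(0.5, abs=0.15)
        assert stats[400][1] < stats[200][1]


class TestTypicality:
    def test_species_equal_to_average_scores_one(self):
        afd = np.tile(np.array([0.2, 0.3, 0.5]), (4, 1))
        dist = obs.AbundanceDistributions(
            edges=np.array([1e-8, 1e-6, 1e-4, 1e-2]), afd=afd,
            mean_afd=afd[0], sd_afd=np.zeros(3),
            snapshot_times=np.array([0.0]), sad=afd.T[:, :1])
        np.testing.assert_allclose(obs.typicality(dist), 1.0)

    def test_three_bin_hand_example(self):
        afd = np.array([[0.5, 0.3, 0.2], [0.2, 0.3, 0.5]])
        mean = np.array([0.2, 0.3, 0.5])
        dist = obs.AbundanceDistributions(
            edges=np.array([1e-8, 1e-6, 1e-4, 1e-2]), afd=afd,
            mean_afd=mean, sd_afd=np.zeros(3),
            snapshot_times=np.array([0.0]), sad=afd.T[:, :1])
        theta = obs.typicality(dist)
        assert theta[0] == pytest.approx(0.7)
        assert theta[1] == pytest.approx(1.0)


class TestSelection:
    def test_disorder_free_limit(self):
        p = dlv.EcologicalParams(S=4, mu=0.5, sigma=0.3, lam=1e-8)
        M = dlv.sample_interactions(p, 0)
        M.alpha[:] = 0.5
        np.fill_diagonal(M.alpha, 0.0)
        x = np.array([[0.4], [0.3], [0.2], [0.1]])
        traj = dlv.Trajectory(times=np.array([0.0]), x=x, params=p,
                              matrix_seed=0, x0_seed=0,
                              settings=dlv.IntegrationSettings())
        dec = obs.selection_decomposition(traj, M)
        np.testing.assert_allclose(dec.s, 0.0, atol=1e-14)
        pvec = x[:, 0] / x.sum()
        assert dec.pi[0] == pytest.approx(np.sum(pvec**2))

    def test_snapshot_matches_double_loop(self):
        p = dlv.EcologicalParams(S=4, mu=0.5, sigma=0.3, lam=1e-8)
        M = dlv.sample_interactions(p, 6)
        x = np.array([[0.4], [0.3], [0.2], [0.1]])
        traj = dlv.Trajectory(times=np.array([0.0]), x=x, params=p,
                              matrix_seed=6, x0_seed=0,
                              settings=dlv.IntegrationSettings())
        dec = obs.selection_decomposition(traj, M)
        z, pvec = M.z, x[:, 0] / x.sum()
        oracle = [-0.3 * sum(z[i, j] * pvec[j] for j in range(4) if j != i)
                  for i in range(4)]
        np.testing.assert_allclose(dec.s[:, 0], oracle, atol=1e-14)

    def test_finite_difference_consistency(self):
        # the exact proportion dynamics must track finite differences of p
        p = dlv.EcologicalParams(S=100, mu=0.5, sigma=0.3, lam=1e-8)
        M = dlv.sample_interactions(p, 3)
        s = dlv.IntegrationSettings(t_burn=500.0, t_run=60.0,
                                    store_stride=0.05, seed_x0=4)
        traj = dlv.integrate(M, dlv.initial_condition(p, s), s)
        assert obs.selection_consistency(traj, M, n_frames=600) > 0.99

    def test_average_bias_proportional_to_z(self, reference_traj,
                                            reference_matrix):
        dec = obs.selection_decomposition(reference_traj, reference_matrix)
        z = reference_matrix.z_bias
        slope = np.polyfit(-z, dec.s_bar, 1)[0]
        assert slope > 0
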