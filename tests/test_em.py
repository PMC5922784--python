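import numpy as np
import pytest

from crossanno import (
    ConfusionModel,
    CountVector,
    FamilyUniverse,
    UnreachableFamilyError,
    corrected_profile,
    e_step,
    fit_plsa,
    m_step,
    observed_log_likelihood,
)
from conftest import count_vector, make_universe, random_model


class TestEStep:
    def test_identity_confusion_gives_diagonal_phi(self, two_family_universe):
        model = ConfusionModel(np.eye(2), np.array([0.4, 0.6]),
                               two_family_universe)
        ws = e_step(model, count_vector(two_family_universe, [3, 7]))
        assert np.allclose(ws.phi, np.diag([3.0, 7.0]))
        assert np.allclose(ws.psi, [3.0, 7.0])

    def test_direct_bayes_split(self):
        universe = FamilyUniverse(("A1",), ("C1", "EXTRA"))
        model = ConfusionModel(np.array([[1.0, 1.0]]), np.array([0.4, 0.6]),
                               universe)
        ws = e_step(model, CountVector(("A1",), np.array([10])))
        assert np.allclose(ws.phi, [[4.0, 6.0]])

    def test_zero_count_rows_are_zero(self, two_family_universe):
        model = ConfusionModel(np.full((2, 2), 0.5), np.array([0.5, 0.5]),
                               two_family_universe)
        ws = e_step(model, count_vector(two_family_universe, [0, 8]))
        assert np.allclose(ws.phi[0], 0.0)
        assert ws.psi.sum() == pytest.approx(8.0)

    def test_unreachable_family_raises(self, two_family_universe):
        alpha = np.array([[0.0, 0.0], [1.0, 1.0]])
        model = ConfusionModel(alpha, np.array([0.5, 0.5]),
                               two_family_universe)
        with pytest.raises(UnreachableFamilyError, match="A000"):
            e_step(model, count_vector(two_family_universe, [5, 5]))

    def test_matches_per_read_brute_force(self, rng):
        model = random_model(rng, 5, 4)
        y = count_vector(model.universe, rng.integers(0, 30, size=5))
        ws = e_step(model, y)
        # accumulate the posterior read by read
        expected = np.zeros((5, 4))
        for i in range(5):
            joint = model.alpha[i] * model.beta
            posterior = joint / joint.sum()
            for _ in range(int(y.counts[i])):
                expected[i] += posterior
        assert np.abs(ws.phi - expected).max() < 1e-9

    def test_read_conservation(self, rng):
        model = random_model(rng, 8, 5)
        y = count_vector(model.universe, rng.integers(0, 100, size=8))
        ws = e_step(model, y)
        assert np.abs(ws.phi.sum(axis=1) - y.counts).max() < 1e-6
        assert ws.psi.sum() == pytest.approx(y.total, abs=1e-6)


class TestMStep:
    def test_diagonal_phi(self):
        from crossanno.em import EMWorkspace

        ws = EMWorkspace(phi=np.diag([3.0, 7.0]), psi=np.array([3.0, 7.0]))
        alpha, beta = m_step(ws)
        assert np.allclose(alpha, np.eye(2))
        assert np.allclose(beta, [0.3, 0.7])

    def test_column_normalization(self):
        from crossanno.em import EMWorkspace

        phi = np.array([[2.0, 1.0], [2.0, 3.0]])
        ws = EMWorkspace(phi=phi, psi=phi.sum(axis=0))
        alpha, beta = m_step(ws)
        assert np.allclose(alpha[:, 0], [0.5, 0.5])
        assert np.allclose(alpha, phi / phi.sum(axis=0))
        assert np.allclose(beta, phi.sum(axis=0) / phi.sum())

    def test_zero_psi_column_keeps_previous_alpha(self):
        from crossanno.em import EMWorkspace

        phi = np.array([[4.0, 0.0], [6.0, 0.0]])
        ws = EMWorkspace(phi=phi, psi=phi.sum(axis=0))
        previous = np.array([[0.9, 0.2], [0.1, 0.8]])
        alpha, beta = m_step(ws, previous_alpha=previous)
        assert np.allclose(alpha[:, 1], previous[:, 1])
        assert beta[1] < 1e-10
        assert beta.sum() == pytest.approx(1.0)

    def test_simplex_outputs_on_random_workspace(self, rng):
        from crossanno.em import EMWorkspace

        phi = rng.uniform(0.1, 5.0, size=(6, 4))
        ws = EMWorkspace(phi=phi, psi=phi.sum(axis=0))
        alpha, beta = m_step(ws)
        assert np.abs(alpha.sum(axis=0) - 1.0).max() < 1e-12
        assert beta.sum() == pytest.approx(1.0, abs=1e-12)


class TestObservedLogLikelihood:
    def test_identity_closed_form(self, two_family_universe):
        model = ConfusionModel(np.eye(2), np.array([0.5, 0.5]),
                               two_family_universe)
        ll = observed_log_likelihood(
            model, count_vector(two_family_universe, [1, 1])
        )
        assert ll == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_single_positive_count(self):
        universe = FamilyUniverse(("A1", "A2"), ("C1", "EXTRA"))
        alpha = np.array([[0.3, 0.5], [0.7, 0.5]])
        beta = np.array([0.6, 0.4])
        model = ConfusionModel(alpha, beta, universe)
        y = CountVector(("A1", "A2"), np.array([5, 0]))
        p = alpha[0] @ beta
        assert observed_log_likelihood(model, y) == pytest.approx(
            5 * np.log(p), abs=1e-12
        )

    def test_scaling_counts_scales_loglik(self, rng):
        model = random_model(rng, 4, 3)
        counts = rng.integers(1, 20, size=4)
        y1 = count_vector(model.universe, counts)
        y3 = count_vector(model.universe, 3 * counts)
        assert observed_log_likelihood(model, y3) == pytest.approx(
            3 * observed_log_likelihood(model, y1), rel=1e-12
        )

    def test_matches_per_read_sum(self, rng):
        model = random_model(rng, 5, 4)
        y = count_vector(model.universe, rng.integers(0, 15, size=5))
        expected = 0.0
        marginal = model.alpha @ model.beta
        for i in range(5):
            for _ in range(int(y.counts[i])):
                expected += np.log(marginal[i])
        assert observed_log_likelihood(model, y) == pytest.approx(
            expected, abs=1e-9
        )

    def test_zero_marginal_warns_minus_inf(self):
        universe = FamilyUniverse(("A1", "A2"), ("C1", "EXTRA"))
        alpha = np.array([[0.0, 0.0], [1.0, 1.0]])
        model = ConfusionModel(alpha, np.array([0.5, 0.5]), universe)
        y = CountVector(("A1", "A2"), np.array([2, 2]))
        with pytest.warns(RuntimeWarning):
            assert observed_log_likelihood(model, y) == float("-inf")


class TestFitPlsa:
    def test_identity_alpha_converges_to_empirical(self, rng):
        universe = make_universe(4, 4)
        y = count_vector(universe, [10, 20, 30, 40])
        result = fit_plsa(np.eye(4), np.full(4, 0.25), y, universe)
        assert result.converged
        assert result.iterations <= 2
        assert np.array_equal(result.model.beta, y.counts / y.total)

    def test_single_origin_degenerate(self):
        universe = FamilyUniverse(("A1", "A2"), ("EXTRA",))
        y = CountVector(("A1", "A2"), np.array([30, 70]))
        result = fit_plsa(
            np.array([[0.5], [0.5]]), np.array([1.0]), y, universe
        )
        assert result.converged
        assert result.model.beta[0] == pytest.approx(1.0)
        assert np.allclose(result.model.alpha[:, 0], [0.3, 0.7])

    def test_monotone_loglik_on_random_instances(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 8))
            m = int(rng.integers(2, n + 2))
            model = random_model(rng, n, m)
            y = count_vector(model.universe, rng.integers(0, 50, size=n))
            if y.total == 0:
                continue
            init = random_model(rng, n, m)
            result = fit_plsa(init.alpha, init.beta, y, model.universe,
                              max_iter=200)
            trace = np.array(result.loglik_trace)
            assert (np.diff(trace) >= -1e-9).all()

    def test_beta_only_fit_matches_grid_search(self):
        """With alpha fixed the likelihood is concave in beta; EM must land
        on the same maximizer as a fine grid over the 2-simplex edge."""
        universe = FamilyUniverse(("A1", "A2"), ("C1", "EXTRA"))
        alpha = np.array([[0.8, 0.3], [0.2, 0.7]])
        y = CountVector(("A1", "A2"), np.array([18, 12]))
        counts = y.counts.astype(float)

        grid = np.arange(0.0, 1.0 + 1e-12, 1e-3)
        best_b, best_ll = None, -np.inf
        for b in grid:
            marginal = alpha @ np.array([b, 1.0 - b])
            if (marginal <= 0).any():
                continue
            ll = counts @ np.log(marginal)
            if ll > best_ll:
                best_b, best_ll = b, ll

        result = fit_plsa(alpha, np.array([0.5, 0.5]), y, universe,
                          update_alpha=False)
        assert result.converged
        assert np.allclose(result.model.alpha, alpha)
        assert abs(result.model.beta[0] - best_b) <= 1e-3

    def test_fit_is_deterministic(self, rng):
        model = random_model(rng, 6, 4)
        y = count_vector(model.universe, rng.integers(1, 60, size=6))
        init = random_model(rng, 6, 4)
        r1 = fit_plsa(init.alpha, init.beta, y, model.universe)
        r2 = fit_plsa(init.alpha, init.beta, y, model.universe)
        assert np.array_equal(r1.model.beta, r2.model.beta)
        assert np.array_equal(r1.model.alpha, r2.model.alpha)
        assert r1.loglik_trace == r2.loglik_trace

    def test_parameter_recovery_from_true_alpha(self, rng):
        """Data simulated from a known model, fitted with alpha held at the
        truth and beta started uniform, recovers beta at sampling-error
        scale. (With alpha also free the decomposition is not identifiable
        from a flat start — hence the learned initialization.)"""
        from crossanno import SimulationConfig, sample_truth, simulate_counts

        config = SimulationConfig(n_existing=10, n_aligned=15, seed=5)
        model = sample_truth(config)
        y = simulate_counts(model, 100_000, seed=6, labeled=False)
        m = model.universe.n_existing
        result = fit_plsa(model.alpha, np.full(m, 1.0 / m), y,
                          model.universe, max_iter=2000,
                          update_alpha=False)
        tv = 0.5 * np.abs(result.model.beta - model.beta).sum()
        assert tv < 0.02


class TestCorrectedProfile:
    def test_rounding(self):
        universe = FamilyUniverse(("A1", "A2"), ("C1", "EXTRA"))
        y = CountVector(("A1", "A2"), np.array([74, 26]))
        result = fit_plsa(np.eye(2), np.array([0.5, 0.5]), y, universe)
        profile = corrected_profile(result, y)
        assert list(profile.count_hat) == [74, 26]
        # explicit rounding example: beta (0.256, 0.744) of 100
        from crossanno.em import EMResult, ConfusionModel

        model = ConfusionModel(np.eye(2), np.array([0.256, 0.744]), universe)
        fake = EMResult(model, (0.0,), 1, True)
        y100 = CountVector(("A1", "A2"), np.array([40, 60]))
        profile = corrected_profile(fake, y100)
        assert list(profile.count_hat) == [26, 74]

    def test_rounding_slack_bound(self, rng):
        universe = make_universe(30, 30)
        for _ in range(20):
            beta = rng.dirichlet(np.ones(30))
            counts = rng.multinomial(100_000, beta)
            y = count_vector(universe, counts)
            result = fit_plsa(np.eye(30), np.full(30, 1 / 30), y, universe)
            profile = corrected_profile(result, y)
            assert abs(int(profile.count_hat.sum()) - y.total) <= 15
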