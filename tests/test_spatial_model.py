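import numpy as np
import pytest
from scipy import stats

from geosurv.data_model import build_region_graph
from geosurv.spatial_model import (
    EFFECTIVE_RANGE_FACTOR,
    ModelState,
    car_covariance,
    car_logpdf,
    car_precision,
    effective_range,
    gp_covariance,
    log_posterior,
    log_posterior_parts,
    mvn_logpdf_chol,
    rho_bounds,
    scale_coverage,
)
from geosurv.survival_core import loglik


class TestGpCovariance:
    def test_diagonal_is_sigma2(self):
        d = np.array([[0.0, 5.0], [5.0, 0.0]])
        cov = gp_covariance(d, 2.0, 0.1, jitter=0.0)
        assert np.allclose(np.diag(cov), 2.0)

    def test_value_at_effective_range(self):
        rho = 0.08
        d_eff = EFFECTIVE_RANGE_FACTOR / rho
        d = np.array([[0.0, d_eff], [d_eff, 0.0]])
        cov = gp_covariance(d, 3.0, rho, jitter=0.0)
        assert cov[0, 1] == pytest.approx(0.05 * 3.0, abs=1e-12)

    def test_matches_elementwise_scalar_evaluation(self, rng):
        d = rng.uniform(0, 100, (5, 5))
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        cov = gp_covariance(d, 1.7, 0.04, jitter=0.0)
        for i in range(5):
            for j in range(5):
                assert cov[i, j] == pytest.approx(1.7 * np.exp(-d[i, j] * 0.04), abs=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(Exception):
            gp_covariance(np.zeros((2, 3)), 1.0, 0.1)


class TestRhoBounds:
    def test_two_distance_example(self):
        d = np.array([[0.0, 10.0, 100.0], [10.0, 0.0, 90.0], [100.0, 90.0, 0.0]])
        a, b = rho_bounds(d)
        assert a == pytest.approx(EFFECTIVE_RANGE_FACTOR / 100.0)  # ~0.03
        assert b == pytest.approx(EFFECTIVE_RANGE_FACTOR / 10.0)   # ~0.3

    def test_inverse_relation_with_effective_range(self):
        d = np.array([[0.0, 25.0], [25.0, 0.0]])
        a, b = rho_bounds(d)
        assert effective_range(a) == pytest.approx(25.0)
        assert effective_range(b) == pytest.approx(25.0)

    def test_duplicate_coordinates_skip_zero_distances(self):
        d = np.array([[0.0, 0.0, 40.0], [0.0, 0.0, 40.0], [40.0, 40.0, 0.0]])
        a, b = rho_bounds(d)
        assert b == pytest.approx(EFFECTIVE_RANGE_FACTOR / 40.0)

    def test_all_coincident_rejected(self):
        with pytest.raises(Exception, match="coincide"):
            rho_bounds(np.zeros((3, 3)))


class TestCarCovariance:
    def test_gamma_zero_gives_scaled_D(self, path_graph):
        cov = car_covariance(path_graph, 2.0, 0.0)
        assert np.allclose(cov, 2.0 * path_graph.D)

    def test_two_region_hand_inverse(self):
        graph = build_region_graph([("A", "B")])
        cov = car_covariance(graph, 1.0, 0.5)
        assert np.allclose(cov, [[4 / 3, 2 / 3], [2 / 3, 4 / 3]], atol=1e-12)

    def test_symmetric_pd_on_random_graph(self, rng):
        nodes = [f"r{i}" for i in range(6)]
        edges = [(nodes[i], nodes[i + 1]) for i in range(5)] + [(nodes[0], nodes[4])]
        graph = build_region_graph(edges)
        lo, hi = graph.gamma_bounds
        gamma = lo + 0.8 * (hi - lo)
        cov = car_covariance(graph, 0.6, gamma)
        assert np.allclose(cov, cov.T, atol=1e-10)
        assert np.linalg.eigvalsh(cov)[0] > 0

    def test_gamma_at_bound_rejected(self, path_graph):
        with pytest.raises(ValueError):
            car_covariance(path_graph, 1.0, path_graph.gamma_bounds[1])

    def test_precision_is_inverse(self, path_graph):
        cov = car_covariance(path_graph, 0.9, 0.4)
        prec = car_precision(path_graph, 0.9, 0.4)
        assert np.allclose(cov @ prec, np.eye(3), atol=1e-10)

    def test_logpdf_matches_scipy(self, path_graph, rng):
        w = rng.normal(0, 0.5, 3)
        sigmaq2, gamma = 0.8, 0.3
        expected = stats.multivariate_normal(
            mean=np.zeros(3), cov=car_covariance(path_graph, sigmaq2, gamma)
        ).logpdf(w)
        assert car_logpdf(w, path_graph, sigmaq2, gamma) == pytest.approx(expected, abs=1e-10)


class TestLogPosterior:
    def _state(self, data, rng=None):
        state = data.initial_state()
        if rng is not None:
            state.beta = rng.normal(0, 0.3, len(state.beta))
            state.a = float(rng.normal(0, 0.1))
            state.w = rng.normal(0, 0.2, data.n_regions)
            state.phi = rng.normal(0, 0.2, data.n_clusters)
        return state

    def test_equals_hand_assembled_component_sum(self, tiny_model, rng):
        state = self._state(tiny_model, rng)
        parts = log_posterior_parts(state, tiny_model)
        # independent re-assembly of each component
        surv = loglik(tiny_model.times, tiny_model.events, tiny_model.eta(state), state.delta)
        gp = stats.multivariate_normal(
            mean=np.zeros(4),
            cov=gp_covariance(tiny_model.distances, state.sigma2, state.rho),
        ).logpdf(state.phi)
        car = stats.multivariate_normal(
            mean=np.zeros(2),
            cov=car_covariance(tiny_model.region_graph, state.sigmaq2, state.gamma),
        ).logpdf(state.w)
        pri = (
            stats.invgamma(2.01, scale=1.01).logpdf(state.sigma2)
            + stats.invgamma(2.01, scale=1.01).logpdf(state.sigmaq2)
            + stats.expon(scale=100.0).logpdf(state.delta)
            + stats.norm(scale=np.sqrt(1e3)).logpdf(state.beta).sum()
            + stats.norm(scale=np.sqrt(1e3)).logpdf(state.a)
            - np.log(tiny_model.priors.rho_support[1] - tiny_model.priors.rho_support[0])
            - np.log(tiny_model.priors.gamma_support[1] - tiny_model.priors.gamma_support[0])
        )
        assert parts["survival"] == pytest.approx(surv, abs=1e-8)
        assert parts["gp"] == pytest.approx(gp, abs=1e-6)
        assert parts["car"] == pytest.approx(car, abs=1e-8)
        assert parts["prior"] == pytest.approx(pri, abs=1e-8)
        assert log_posterior(state, tiny_model) == pytest.approx(sum(parts.values()), abs=1e-8)

    def test_survival_term_invariant_to_phi_intercept_tradeoff(self, tiny_model, rng):
        state = self._state(tiny_model, rng)
        shifted = state.copy()
        shifted.phi = state.phi + 0.7
        shifted.beta = state.beta.copy()
        shifted.beta[0] -= 0.7  # intercept column absorbs the shift
        a = log_posterior_parts(state, tiny_model)["survival"]
        b = log_posterior_parts(shifted, tiny_model)["survival"]
        assert a == pytest.approx(b, abs=1e-9)

    def test_outside_support_is_minus_inf_not_exception(self, tiny_model):
        state = self._state(tiny_model)
        state.sigma2 = -1.0
        assert log_posterior(state, tiny_model) == -np.inf
        state = self._state(tiny_model)
        state.gamma = 99.0
        assert log_posterior(state, tiny_model) == -np.inf

    def test_inverse_gamma_prior_mode(self):
        # mode of IG(shape, scale) = scale / (shape + 1)
        dist = stats.invgamma(2.01, scale=1.01)
        grid = np.linspace(0.01, 3.0, 20000)
        assert grid[np.argmax(dist.pdf(grid))] == pytest.approx(1.01 / 3.01, abs=1e-3)


class TestCoverageScaling:
    def test_per10pp_unit(self):
        assert scale_coverage(0.45, "per10pp") == pytest.approx(4.5)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            scale_coverage(0.5, "furlongs")


def test_mvn_logpdf_matches_scipy(rng):
    cov = np.array([[2.0, 0.3], [0.3, 1.0]])
    x = rng.normal(0, 1, 2)
    assert mvn_logpdf_chol(x, cov) == pytest.approx(
        stats.multivariate_normal(mean=np.zeros(2), cov=cov).logpdf(x), abs=1e-10
    )
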