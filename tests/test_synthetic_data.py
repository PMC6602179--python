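import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geosurv.data_model import build_region_graph
from geosurv.spatial_model import EFFECTIVE_RANGE_FACTOR
from geosurv.synthetic_data import (
    SimulationConfig,
    generate_survey,
    make_grid_region_graph,
    simulate_frailty,
    simulate_regional_effects,
    simulate_survival_times,
)


class TestFrailty:
    def test_independence_in_fast_decay_limit(self, rng):
        # two clusters 10 km apart with d*rho = 50: essentially independent
        d = np.array([[0.0, 10.0], [10.0, 0.0]])
        draws = np.array([simulate_frailty(d, 1.0, 5.0, rng) for _ in range(2000)])
        corr = np.corrcoef(draws.T)[0, 1]
        assert abs(corr) < 0.05

    def test_correlation_at_effective_range(self, rng):
        rho = 0.1
        d_eff = EFFECTIVE_RANGE_FACTOR / rho
        d = np.array([[0.0, d_eff], [d_eff, 0.0]])
        draws = np.array([simulate_frailty(d, 1.0, rho, rng) for _ in range(5000)])
        corr = np.corrcoef(draws.T)[0, 1]
        assert corr == pytest.approx(0.05, abs=0.04)

    def test_marginal_variance(self, rng):
        d = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0))) * 20.0
        sigma2 = 0.8
        draws = np.array([simulate_frailty(d, sigma2, 0.05, rng) for _ in range(5000)])
        var = draws.var(axis=0, ddof=1)
        assert np.all(np.abs(var / sigma2 - 1.0) < 0.10)

    def test_zero_variance_shortcut(self):
        d = np.zeros((3, 3))
        assert np.all(simulate_frailty(d, 0.0, 0.1, 1) == 0.0)


class TestRegionalEffects:
    def test_gamma_zero_is_scaled_independent(self, rng):
        graph = build_region_graph([("A", "B")])
        draws = np.array(
            [simulate_regional_effects(graph, 1.0, 0.0, rng) for _ in range(4000)]
        )
        corr = np.corrcoef(draws.T)[0, 1]
        assert abs(corr) < 0.06
        assert np.allclose(draws.var(axis=0, ddof=1), 1.0, atol=0.12)

    def test_path_graph_covariance_matches_inverse_oracle(self, path_graph, rng):
        sigmaq2, gamma = 0.7, 0.5
        # independent oracle: direct 3x3 inverse of (I - gamma C) times D
        oracle = sigmaq2 * np.linalg.inv(np.eye(3) - gamma * path_graph.C) @ path_graph.D
        draws = np.array(
            [simulate_regional_effects(path_graph, sigmaq2, gamma, rng) for _ in range(10000)]
        )
        emp = np.cov(draws.T)
        scale = np.sqrt(np.outer(np.diag(oracle), np.diag(oracle)))
        assert np.all(np.abs(emp - oracle) <= 0.05 * scale)

    def test_zero_mean(self, path_graph, rng):
        draws = np.array(
            [simulate_regional_effects(path_graph, 0.5, 0.3, rng) for _ in range(10000)]
        )
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0)) < 3.0 * se)

    def test_gamma_outside_bounds_rejected(self, path_graph):
        with pytest.raises(ValueError, match="gamma"):
            simulate_regional_effects(path_graph, 1.0, 5.0, 0)


class TestSurvivalTimes:
    def test_unit_exponential_special_case(self, rng):
        t = simulate_survival_times(np.zeros(100_000), 1.0, rng)
        assert t.mean() == pytest.approx(1.0, abs=0.02)

    def test_rate_two_exponential(self, rng):
        t = simulate_survival_times(np.full(100_000, np.log(2.0)), 1.0, rng)
        assert t.mean() == pytest.approx(0.5, abs=0.01)

    def test_cdf_matches_closed_form(self, rng):
        delta, eta = 0.6, -1.1
        t = simulate_survival_times(np.full(100_000, eta), delta, rng)
        for q in (1.0, 5.0, 20.0):
            expected = 1.0 - np.exp(-(q**delta) * np.exp(eta))
            assert (t <= q).mean() == pytest.approx(expected, abs=0.01)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            simulate_survival_times(np.zeros(3), 0.0, 1)


class TestGenerateSurvey:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_regions=6, n_clusters=15, n_children=300, seed=3)
        generate_survey(cfg, out_dir=tmp_path / "a")
        generate_survey(cfg, out_dir=tmp_path / "b")
        for name in ("children.csv", "clusters.csv", "coverage.csv", "adjacency.txt", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_protective_effect_lowers_mortality_in_high_coverage_regions(self):
        # isolate the intervention effect: no spatial noise, no covariates
        cfg = SimulationConfig(
            n_regions=8,
            n_clusters=40,
            n_children=50_000,
            true_a=np.log(0.9),
            true_sigma2=0.0,
            true_sigmaq2=0.0,
            true_beta={},
            covariate_marginals={},
            baseline_log_hazard=-2.0,
            seed=9,
        )
        survey = generate_survey(cfg)
        merged = survey.children.merge(
            survey.spatial_frame.region_of.rename("region_id"),
            left_on="cluster_id",
            right_index=True,
        )
        death_by_region = merged.groupby("region_id")["event"].mean()
        coverage = survey.coverage[cfg.intervention]
        tau, p = stats.kendalltau(coverage.loc[death_by_region.index], death_by_region)
        assert tau < 0
        assert p < 0.01

    def test_default_preset_death_fraction_near_nine_percent(self):
        survey = generate_survey(SimulationConfig(seed=0))
        assert 0.06 <= survey.children["event"].mean() <= 0.12

    def test_km_matches_closed_form_without_random_effects(self):
        from geosurv.survival_core import km_5q0
        from lifelines import KaplanMeierFitter

        cfg = SimulationConfig(
            n_regions=4,
            n_clusters=10,
            n_children=100_000,
            true_sigma2=0.0,
            true_sigmaq2=0.0,
            true_a=0.0,
            true_beta={},
            covariate_marginals={},
            baseline_log_hazard=-3.0,
            seed=21,
        )
        survey = generate_survey(cfg)
        km = KaplanMeierFitter().fit(
            survey.children["time_months"], survey.children["event"]
        )
        for t0 in (12.0, 36.0, 60.0):
            closed = np.exp(-(t0**cfg.true_delta) * np.exp(cfg.baseline_log_hazard))
            est = float(km.survival_function_at_times(t0).iloc[0])
            assert est == pytest.approx(closed, abs=0.01)
        assert km_5q0(survey.children["time_months"], survey.children["event"]) > 0

    def test_censoring_increases_as_window_shrinks(self):
        fractions = []
        for window in (60.0, 40.0, 20.0):
            cfg = SimulationConfig(
                n_regions=6, n_clusters=20, n_children=30_000,
                interview_window_months=window, seed=4,
            )
            survey = generate_survey(cfg)
            fractions.append(1.0 - survey.children["event"].mean())
        assert fractions[0] < fractions[1] < fractions[2]

    def test_invalid_marginals_rejected_before_writing(self, tmp_path):
        cfg = SimulationConfig(covariate_marginals={"sex": {"female": 0.6, "male": 0.6}})
        with pytest.raises(ValueError, match="marginals"):
            generate_survey(cfg, out_dir=tmp_path)
        assert not (tmp_path / "children.csv").exists()

    def test_truth_records_all_parameters(self):
        cfg = SimulationConfig(n_regions=5, n_clusters=10, n_children=100, seed=2)
        survey = generate_survey(cfg)
        for key in ("delta", "a", "sigma2", "rho", "sigmaq2", "gamma", "w", "phi"):
            assert key in survey.truth
        assert len(survey.truth["w"]) == 5
        assert len(survey.truth["phi"]) == 10


def test_grid_graph_connected_for_odd_sizes():
    for q in (5, 9, 13):
        graph, centers = make_grid_region_graph(q)
        assert graph.n_regions == q
        assert len(centers) == q
        assert np.all(graph.g >= 1)
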