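import numpy as np
import pandas as pd
import pytest

from sprforest import (
    DEFAULT_DESIGNS,
    DesignSpec,
    ExperimentConfig,
    PopulationParams,
    draw_samples,
    run_experiment,
    summarize_experiment,
)
from sprforest.errors import ConfigError, DesignError
from sprforest.montecarlo import PanelSource, expected_true_change, run_iteration
from sprforest.scenarios import DEFAULT_SCENARIOS, ScenarioSpec


class TestDesignSpec:
    def test_defaults_are_consistent(self):
        for d in DEFAULT_DESIGNS:
            d.validate()
            assert d.n_occ1 == d.n_occ2 == 375

    def test_invalid_combinations(self):
        with pytest.raises(ConfigError):
            DesignSpec("temporary", 10, 5, 10).validate()
        with pytest.raises(ConfigError):
            DesignSpec("cfi", 1, 10, 0).validate()
        with pytest.raises(ConfigError):
            DesignSpec("spr", 5, 2, 5).validate()


class TestDrawSamples:
    def test_cfi_single_matched_sample(self, rng):
        roles = draw_samples(750, DesignSpec("cfi", 0, 375, 0), rng)
        assert len(roles.permanent) == 375
        assert len(np.unique(roles.permanent)) == 375
        assert roles.t1_only.size == roles.t2_only.size == 0

    def test_spr_disjoint_new_plots(self, rng):
        d = DesignSpec("spr", 125, 250, 125)
        roles = draw_samples(750, d, rng)
        occ1 = np.concatenate([roles.t1_only, roles.permanent])
        assert occ1.size == 375 and np.unique(occ1).size == 375
        assert roles.permanent.size == 250
        assert np.intersect1d(occ1, roles.t2_only).size == 0  # new plots are new
        assert roles.t2_only.size == 125

    def test_temporary_independent_draws(self, rng):
        d = DesignSpec("temporary", 375, 0, 375)
        roles = draw_samples(750, d, rng)
        assert roles.t1_only.size == roles.t2_only.size == 375
        assert roles.permanent.size == 0

    def test_partition_when_population_exactly_fits(self, rng):
        d = DesignSpec("spr", 10, 20, 10)
        roles = draw_samples(40, d, rng)
        everything = np.concatenate([roles.t1_only, roles.permanent, roles.t2_only])
        assert np.array_equal(np.sort(everything), np.arange(1, 41))

    def test_oversized_design_rejected(self, rng):
        with pytest.raises(DesignError):
            draw_samples(100, DesignSpec("cfi", 0, 375, 0), rng)
        with pytest.raises(DesignError):
            draw_samples(30, DesignSpec("spr", 10, 20, 10), rng)  # no room for new


@pytest.fixture(scope="module")
def small_cfg():
    return ExperimentConfig(
        population=PopulationParams(n_plots=60, seed=11),
        scenarios=(DEFAULT_SCENARIOS[0], DEFAULT_SCENARIOS[4], DEFAULT_SCENARIOS[5]),
        designs=(
            DesignSpec("temporary", 30, 0, 30),
            DesignSpec("cfi", 0, 30, 0),
            DesignSpec("spr", 10, 20, 10),
        ),
        iterations=8,
        master_seed=99,
    )


class TestRunExperiment:
    def test_deterministic(self, small_cfg):
        a = run_experiment(small_cfg)
        b = run_experiment(small_cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_truth_shared_within_iteration(self, small_cfg):
        res = run_experiment(small_cfg)
        per_cell = res.groupby(["scenario", "iteration"])["truth_change"].nunique()
        assert (per_cell == 1).all()

    def test_no_intervention_bias_flag_inert(self, small_cfg):
        res = run_experiment(small_cfg)
        g = res[res.scenario == "no_intervention"]
        wide = g.pivot_table(index=["design", "iteration"], columns="bias",
                             values="change")
        np.testing.assert_allclose(wide[False], wide[True])

    def test_row_count_and_columns(self, small_cfg):
        res = run_experiment(small_cfg)
        assert len(res) == 3 * 3 * 2 * 8
        assert {"scenario", "design", "bias", "iteration", "change", "se",
                "truth_change"} <= set(res.columns)

    def test_single_iteration_allowed(self, small_cfg):
        cfg = ExperimentConfig(
            population=small_cfg.population, scenarios=small_cfg.scenarios[:1],
            designs=small_cfg.designs[:1], iterations=1, master_seed=1)
        assert len(run_experiment(cfg)) == 2  # one per bias variant


class TestSummaries:
    def test_shapes_and_counts(self, small_cfg):
        res = run_experiment(small_cfg)
        summ = summarize_experiment(res)
        assert len(summ) == 3 * 3 * 2
        assert (summ["iterations"] == 8).all()
        assert (summ["empirical_sd"] >= 0).all()

    def test_estimates_equal_truth_give_100_percent(self):
        res = pd.DataFrame(
            {"scenario": "s", "design": "cfi", "bias": False,
             "iteration": [0, 1, 2], "change": [2.0, 2.0, 2.0],
             "variance": 0.0, "se": 0.0, "truth_change": [2.0, 2.0, 2.0]}
        )
        summ = summarize_experiment(res)
        assert summ["pct_of_true"].iloc[0] == pytest.approx(100.0)
        assert summ["empirical_sd"].iloc[0] == 0.0
        assert summ["mean_abs_error"].iloc[0] == 0.0


class TestBiasMechanism:
    def test_permanent_plots_observe_undisturbed_under_bias(self):
        source = PanelSource.from_params(PopulationParams(n_plots=50, seed=3))
        spec = ScenarioSpec("defor", 1.0, "remove_all")
        d = DesignSpec("cfi", 0, 25, 0)
        rng = np.random.default_rng(1)
        affected = np.arange(1, 51)
        biased = run_iteration(source, spec, d, True, None,
                               np.random.default_rng(7), affected=affected)
        honest = run_iteration(source, spec, d, False, None,
                               np.random.default_rng(7), affected=affected)
        # full deforestation: truth is a total loss, the biased permanent
        # sample still sees growth
        assert honest.estimate.change == pytest.approx(-source.x.mean(), rel=0.3)
        assert biased.estimate.change > 0
        assert biased.truth.change == honest.truth.change

    def test_expected_true_change_matches_empirical(self):
        source = PanelSource.from_params(PopulationParams(n_plots=80, seed=21))
        spec = ScenarioSpec("deg", 0.25, "remove_above", 45.0)
        exp = expected_true_change(source, spec)
        rng = np.random.default_rng(0)
        draws = []
        from sprforest.scenarios import select_affected_plots

        for _ in range(400):
            affected = select_affected_plots(80, 0.25, rng)
            y = source.y_undist.copy()
            col = source.disturbed_column(spec)
            y[affected - 1] = col[affected - 1]
            draws.append(y.mean() - source.x.mean())
        assert np.mean(draws) == pytest.approx(exp, abs=3 * np.std(draws) / 20)
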