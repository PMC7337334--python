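"""Mixture design bookkeeping, battery orchestration, and averaging."""

import numpy as np
import pytest

from sympmix.experiment import (
    BatteryConfig,
    MixtureDesign,
    draw_mixture,
    run_battery,
    run_experiment,
    statistics_from_mean_matrix,
    tidy_results,
)
from sympmix.synthetic import GeneratorConfig, simulate_cohort

FAST = BatteryConfig(pa_kind="pearson", pa_sets=30, path_points=40)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = GeneratorConfig(n_subjects=2500, target_prevalence=0.08, seed=17)
    return simulate_cohort(cfg)


class TestMixtureDesign:
    def test_default_grid_has_22_conditions(self):
        design = MixtureDesign()
        assert design.n_conditions == 22
        assert design.conditions[0] == "dep"
        assert design.conditions[-2:] == ["full", "nondep"]
        assert design.n_replicates == 500

    def test_rejects_non_increasing_proportions(self):
        with pytest.raises(ValueError, match="increasing"):
            MixtureDesign(proportions=(0.5, 0.5))


class TestDrawMixture:
    def test_worked_example_ten_percent_of_356(self):
        rng = np.random.default_rng(0)
        aff = np.arange(356)
        non = np.arange(356, 6000)
        idx = draw_mixture(aff, non, 0.10, rng)
        assert idx.size == 356 + 36

    @pytest.mark.parametrize("proportion, m", [(1.00, 356), (2.00, 712)])
    def test_integer_multiples(self, proportion, m):
        rng = np.random.default_rng(1)
        idx = draw_mixture(np.arange(356), np.arange(356, 6000), proportion, rng)
        assert idx.size == 356 + m

    def test_half_up_rounding(self):
        rng = np.random.default_rng(2)
        # 0.5 * 5 = 2.5 rounds up to 3
        idx = draw_mixture(np.arange(5), np.arange(5, 100), 0.5, rng)
        assert idx.size == 8

    def test_draw_without_replacement_and_strata(self):
        rng = np.random.default_rng(3)
        aff = np.arange(100)
        non = np.arange(100, 400)
        idx = draw_mixture(aff, non, 2.0, rng)
        extra = idx[100:]
        assert np.unique(extra).size == extra.size
        assert np.isin(extra, non).all()

    def test_exhausted_pool_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="non-affected"):
            draw_mixture(np.arange(100), np.arange(100, 150), 1.0, rng)


class TestRunBattery:
    def test_full_sample_recovery(self, small_cohort):
        data, labels, _ = small_cohort
        res = run_battery(data, n_affected=labels.n_affected, config=FAST,
                          rng=np.random.default_rng(0))
        assert res.statistics["pa_components"] == 1
        assert res.statistics["cfi"] >= 0.99
        assert not res.stage_errors

    def test_deterministic_given_fixed_streams(self, small_cohort):
        data, labels, _ = small_cohort
        r1 = run_battery(data, config=FAST, rng=np.random.default_rng(5))
        r2 = run_battery(data, config=FAST, rng=np.random.default_rng(5))
        assert r1.statistics == r2.statistics

    def test_affected_subsample_attenuated(self, small_cohort):
        data, labels, _ = small_cohort
        full = run_battery(data, config=FAST, rng=np.random.default_rng(6))
        dep = run_battery(
            data.subset(np.flatnonzero(labels.affected)),
            config=FAST,
            rng=np.random.default_rng(6),
        )
        assert (
            dep.statistics["average_correlation"]
            < full.statistics["average_correlation"]
        )

    def test_sample_below_minimum_rejected(self, small_cohort):
        data, _, _ = small_cohort
        with pytest.raises(ValueError, match="minimum"):
            run_battery(data.subset(np.arange(10)), config=FAST)


@pytest.fixture(scope="module")
def reduced_result(small_cohort):
    data, labels, _ = small_cohort
    design = MixtureDesign(proportions=(0.5, 1.0), n_replicates=4, seed=99)
    return run_experiment(data, labels, design, FAST), design


class TestRunExperiment:
    def test_bookkeeping_exact_per_condition(self, reduced_result, small_cohort):
        result, design = reduced_result
        data, labels, _ = small_cohort
        n_aff = labels.n_affected
        for prop in design.proportions:
            expected = n_aff + int(np.floor(prop * n_aff + 0.5))
            assert result.sample_sizes[prop]["sample_size"] == expected

    def test_mean_within_replicate_range(self, reduced_result):
        result, _ = reduced_result
        for cond in (0.5, 1.0):
            m = result.means[cond]["average_correlation"]
            sd = result.sds[cond]["average_correlation"]
            assert np.isfinite(m)
            assert sd >= 0

    def test_reproducible_end_to_end(self, small_cohort):
        data, labels, _ = small_cohort
        design = MixtureDesign(proportions=(0.5,), n_replicates=2, seed=7)
        r1 = run_experiment(data, labels, design, FAST)
        r2 = run_experiment(data, labels, design, FAST)
        assert r1.means == r2.means
        assert r1.config_hash == r2.config_hash

    def test_single_replicate_equals_single_battery(self, small_cohort):
        data, labels, _ = small_cohort
        design = MixtureDesign(proportions=(0.5,), n_replicates=1, seed=3)
        result = run_experiment(data, labels, design, FAST)
        # replay the experiment's seeded stream for that condition
        ss = np.random.SeedSequence(design.seed)
        cond_seed = ss.spawn(design.n_conditions)[1]  # after "dep"
        rep_seed = cond_seed.spawn(1)[0]
        rng = np.random.default_rng(rep_seed)
        idx = draw_mixture(
            np.flatnonzero(labels.affected),
            np.flatnonzero(~labels.affected),
            0.5,
            rng,
        )
        direct = run_battery(
            data.subset(idx),
            n_affected=labels.n_affected,
            config=FAST,
            rng=rng,
        )
        for key, value in direct.statistics.items():
            assert result.means[0.5][key] == pytest.approx(value, nan_ok=True)

    def test_infeasible_condition_fails_before_computation(self, small_cohort):
        data, labels, _ = small_cohort
        design = MixtureDesign(proportions=(50.0,), n_replicates=1, seed=1)
        with pytest.raises(ValueError, match="infeasible"):
            run_experiment(data, labels, design, FAST)

    def test_statistics_from_mean_matrix(self, reduced_result):
        result, _ = reduced_result
        alt = statistics_from_mean_matrix(result, 1.0, n=500)
        assert np.isfinite(alt["average_correlation"])
        assert 0 <= alt["cfi"] <= 1


class TestTidyResults:
    def test_long_shape_and_flags(self, small_cohort):
        data, labels, _ = small_cohort
        design = MixtureDesign(proportions=(0.5,), n_replicates=2, seed=5)
        result = run_experiment(data, labels, design, FAST)
        tidy = tidy_results(result)
        n_stats = tidy["statistic"].nunique()
        assert len(tidy) == len(result.conditions) * n_stats
        symbolic = tidy[tidy["single_run"]]
        assert set(symbolic["condition"]) == {"dep", "full", "nondep"}
        assert (symbolic["replicate_sd"] == 0).all()

    def test_round_trip_preserves_values(self, small_cohort, tmp_path):
        import pandas as pd

        data, labels, _ = small_cohort
        design = MixtureDesign(proportions=(0.5,), n_replicates=1, seed=5)
        tidy = tidy_results(run_experiment(data, labels, design, FAST))
        path = tmp_path / "tidy.csv"
        tidy.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert np.allclose(back["mean"], tidy["mean"], equal_nan=True)
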