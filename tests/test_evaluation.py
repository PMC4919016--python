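"""Monte Carlo evaluation: error metrics, scenario runs, replicate
bookkeeping, rank tests and results CSV round trips."""

import numpy as np
import pandas as pd
import pytest

from pcqm import (
    InvalidSpecError,
    InvalidTrueDensityError,
    PatternSpec,
    PointPattern,
    ResultsCSVError,
    ScenarioConfig,
    Window,
    compare_estimator_families,
    compare_orders,
    corrected_numerator,
    published_numerator,
    rbias,
    read_results_csv,
    rrmse,
    run_scenario,
    write_results_csv,
)


class TestMetrics:
    def test_rrmse_hand_values(self):
        assert rrmse([100.0, 100.0], 100.0) == 0.0
        assert rrmse([200.0], 100.0) == pytest.approx(1.0)
        assert rrmse([100.0, 200.0], 100.0) == pytest.approx(np.sqrt(0.5))

    def test_rbias_hand_values(self):
        assert rbias([100.0], 100.0) == 0.0
        assert rbias([150.0, 150.0], 100.0) == pytest.approx(0.5)
        assert rbias([50.0, 150.0], 100.0) == 0.0

    @pytest.mark.parametrize("metric", [rrmse, rbias])
    def test_inputs_validated(self, metric):
        with pytest.raises(InvalidTrueDensityError):
            metric([1.0], 0.0)
        with pytest.raises(InvalidSpecError):
            metric([], 100.0)


@pytest.fixture(scope="module")
def small_result():
    window = Window.from_size(50, 50)
    config = ScenarioConfig(
        scenario_id="unit-small",
        pattern=PatternSpec("random", 800, window),
        sample_sizes=(10, 15),
        orders=(1, 2),
        replicates=30,
        seed=5,
    )
    return run_scenario(config)


class TestRunScenario:
    def test_grid_shapes(self, small_result):
        # 2 sample sizes x 2 orders x 2 families
        assert len(small_result.metrics) == 8
        assert len(small_result.raw) == 8 * 30
        assert (small_result.metrics["n_failed"] == 0).all()
        assert small_result.metrics["true_density"].unique() == [3200.0]

    def test_rrmse_dominates_absolute_bias(self, small_result):
        m = small_result.metrics
        assert (m["rrmse"] >= m["rbias"].abs() - 1e-12).all()

    def test_same_master_seed_replays_bitwise(self, small_result):
        again = run_scenario(small_result.config)
        pd.testing.assert_frame_equal(again.raw, small_result.raw)
        pd.testing.assert_frame_equal(again.metrics, small_result.metrics)

    def test_published_to_corrected_bias_follows_numerator_ratio(self):
        """Both families divide the same distance sum, so per cell
        (RBIAS_pub + 1) = (RBIAS_corr + 1) * N(gk-1)/(gNk-1) exactly."""
        config = ScenarioConfig(
            scenario_id="unit-ratio",
            pattern=PatternSpec("random", 2500, Window.from_size(100, 100)),
            sample_sizes=(30,),
            orders=(1,),
            replicates=100,
            seed=2,
        )
        m = run_scenario(config).metrics.set_index("pcqm_eqn")
        ratio = published_numerator(30, 1) / corrected_numerator(30, 1)
        assert m.loc["published", "rbias"] + 1 == pytest.approx(
            (m.loc["corrected", "rbias"] + 1) * ratio
        )

    def test_fixed_pattern_mode_surveys_the_returned_realization(self):
        config = ScenarioConfig(
            scenario_id="unit-fixed",
            pattern=PatternSpec("random", 500, Window.from_size(50, 50)),
            sample_sizes=(10,),
            orders=(1,),
            replicates=5,
            regenerate="scenario",
            seed=9,
        )
        a = run_scenario(config)
        b = run_scenario(config)
        np.testing.assert_array_equal(a.pattern.points, b.pattern.points)
        pd.testing.assert_frame_equal(a.raw, b.raw)

    def test_failed_replicates_are_marked_not_dropped(self):
        sparse = PointPattern(
            [[20, 20], [80, 30], [50, 80]], Window.from_size(100, 100)
        )
        config = ScenarioConfig(
            scenario_id="unit-sparse",
            pattern=sparse,
            sample_sizes=(5,),
            orders=(3,),
            replicates=4,
            vacancy_policy="redraw",
            seed=0,
        )
        result = run_scenario(config)
        assert (result.metrics["n_failed"] == 4).all()
        assert result.metrics["rrmse"].isna().all()
        assert len(result.raw) == 8  # rows kept for both families
        assert result.raw["status"].str.startswith("failed").all()
        assert result.raw["density_ha"].isna().all()


class TestRankComparisons:
    def test_identical_samples_not_significant(self, rng):
        x = rng.normal(1000.0, 50.0, 200)
        stat, p = compare_estimator_families(x, x.copy())
        assert p == pytest.approx(1.0)

    def test_disjoint_supports_maximally_significant(self, rng):
        a = rng.uniform(0.0, 1.0, 100)
        b = rng.uniform(10.0, 11.0, 100)
        _, p = compare_estimator_families(a, b)
        assert p < 1e-10

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidSpecError):
            compare_estimator_families([], [1.0])

    def test_identical_groups_omnibus_not_significant(self, rng):
        g = rng.normal(5000.0, 300.0, 150)
        result = compare_orders(g, g.copy(), g.copy())
        assert result.pvalue == pytest.approx(1.0)
        assert (result.posthoc["pvalue_adjusted"] == 1.0).all()

    def test_shifted_group_detected(self, rng):
        a = rng.normal(0.0, 1.0, 100)
        b = rng.normal(0.0, 1.0, 100)
        c = rng.normal(10.0, 1.0, 100)  # 10 pooled SDs away
        result = compare_orders(a, b, c)
        assert result.pvalue < 1e-6
        posthoc = result.posthoc.set_index(["group_a", "group_b"])
        assert posthoc.loc[("PCQM1", "PCQM3"), "pvalue_adjusted"] < 1e-6
        assert posthoc.loc[("PCQM1", "PCQM2"), "pvalue_adjusted"] > 0.05

    def test_unadjusted_option(self, rng):
        a, b, c = (rng.normal(0, 1, 50) for _ in range(3))
        result = compare_orders(a, b, c, adjust="none")
        assert (result.posthoc["pvalue_adjusted"] == result.posthoc["pvalue"]).all()


class TestResultsCSV:
    def test_round_trip(self, tmp_path, small_result):
        path = tmp_path / "raw.csv"
        write_results_csv(small_result.raw, path)
        back = read_results_csv(path)
        assert list(back.columns) == list(small_result.raw.columns)
        np.testing.assert_allclose(
            back["density_ha"], small_result.raw["density_ha"], rtol=1e-9
        )

    def test_empty_rows_round_trip(self, tmp_path, small_result):
        path = tmp_path / "empty.csv"
        write_results_csv(small_result.raw.iloc[:0], path)
        assert read_results_csv(path).empty

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("scenario_id,samples\nx,10\n")
        with pytest.raises(ResultsCSVError, match="missing column"):
            read_results_csv(path)

    def test_non_numeric_value_reports_line(self, tmp_path, small_result):
        path = tmp_path / "bad.csv"
        write_results_csv(small_result.raw.head(3), path)
        lines = path.read_text().splitlines()
        lines[2] = lines[2].replace("10", "ten", 1)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ResultsCSVError, match="line 3") as exc_info:
            read_results_csv(path)
        assert exc_info.value.row == 3
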