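import math

import numpy as np
import pytest

from berryflux import (
    CalibrationSpec, ObservationSeries, SimulationConfig, calibrate,
    default_parameters, fit_metrics, match_predictions,
    sensitivity_analysis, sensitivity_coefficient, simulate,
)
from berryflux.evaluate import (
    ABA_DETECTION_THRESHOLD, EvaluationError, SENSITIVITY_CATEGORIES,
    synthetic_observations,
)
from berryflux.params import CALIBRATED


def naive_metrics(y, yhat):
    """Straight-from-the-definitions oracle, scalar loops only."""
    n = len(y)
    mae = sum(abs(a - b) for a, b in zip(y, yhat)) / n
    rmse = math.sqrt(sum((a - b) ** 2 for a, b in zip(y, yhat)) / n)
    nrmse = rmse / (max(y) - min(y))
    ybar = sum(y) / n
    sse = sum((a - b) ** 2 for a, b in zip(y, yhat))
    sst = sum((a - ybar) ** 2 for a in y)
    ef = 1.0 - sse / sst
    a_sum = sum(abs(a - b) for a, b in zip(y, yhat))
    b_sum = sum(abs(a - ybar) for a in y)
    d_r = (1.0 - a_sum / (2 * b_sum) if a_sum <= 2 * b_sum
           else 2 * b_sum / a_sum - 1.0)
    return mae, rmse, nrmse, d_r, ef


class TestFitMetrics:
    def test_perfect_fit(self):
        m = fit_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.MAE, m.RMSE, m.NRMSE) == (0.0, 0.0, 0.0)
        assert m.d_r == 1.0 and m.EF == 1.0

    def test_hand_computed_example(self):
        # y=(0,2), yhat=(1,1): SST=2, sum|y-ybar|=2
        m = fit_metrics([0.0, 2.0], [1.0, 1.0])
        assert m.MAE == 1.0
        assert m.RMSE == 1.0
        assert m.NRMSE == 0.5
        assert m.EF == 0.0
        assert m.d_r == 0.5

    def test_mean_predictor_has_zero_efficiency(self):
        y = [1.0, 4.0, 2.0, 5.0]
        yhat = [3.0] * 4
        assert fit_metrics(y, yhat).EF == pytest.approx(0.0)

    def test_oracle_equivalence_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            y = rng.normal(0, 10, n)
            yhat = y + rng.normal(0, rng.uniform(0.01, 20), n)
            if np.max(y) == np.min(y):
                continue
            m = fit_metrics(y, yhat)
            mae, rmse, nrmse, d_r, ef = naive_metrics(list(y), list(yhat))
            assert m.MAE == pytest.approx(mae, abs=1e-10)
            assert m.RMSE == pytest.approx(rmse, abs=1e-10)
            assert m.NRMSE == pytest.approx(nrmse, abs=1e-10)
            assert m.d_r == pytest.approx(d_r, abs=1e-10)
            assert m.EF == pytest.approx(ef, abs=1e-10)
            # structural bounds
            assert m.MAE <= m.RMSE + 1e-12
            assert m.EF <= 1.0 and m.d_r <= 1.0

    def test_degenerate_observations_rejected(self):
        with pytest.raises(EvaluationError):
            fit_metrics([2.0, 2.0], [1.0, 3.0])
        with pytest.raises(EvaluationError):
            fit_metrics([1.0], [1.0])


class TestObservations:
    def test_daa_must_increase(self):
        with pytest.raises(EvaluationError):
            ObservationSeries(daa=[10.0, 10.0], fresh_mg=[1.0, 2.0])

    def test_censoring_below_detection_floor(self):
        obs = ObservationSeries(daa=[10.0, 20.0, 30.0],
                                aba_ug_per_g=[5.0, 15.0, np.nan])
        assert ABA_DETECTION_THRESHOLD == 10.0
        assert list(obs.aba_censored) == [True, False, True]

    def test_csv_round_trip(self, tmp_path):
        obs = ObservationSeries(daa=[10.0, 20.0], fresh_mg=[100.0, 300.0],
                                aba_ug_per_g=[2.0, 12.0])
        f = tmp_path / "obs.csv"
        obs.to_csv(f)
        back = ObservationSeries.from_csv(f)
        np.testing.assert_allclose(back.fresh_mg, obs.fresh_mg)
        np.testing.assert_allclose(back.aba_ug_per_g, obs.aba_ug_per_g)


class TestMatchPredictions:
    def test_pairs_at_nearest_hour(self, default_result):
        obs = ObservationSeries(daa=[10.0], fresh_mg=[123.0])
        y, yhat = match_predictions(default_result, obs, "fresh")
        assert y[0] == 123.0
        assert yhat[0] == default_result.table["fresh_mg"].iloc[240]

    def test_censored_aba_excluded(self, default_result):
        obs = synthetic_observations(default_result)
        y, yhat = match_predictions(default_result, obs, "aba")
        assert len(y) == int(np.sum(~obs.aba_censored))
        assert np.all(y > ABA_DETECTION_THRESHOLD)

    def test_outside_span_errors(self, default_result):
        obs = ObservationSeries(daa=[99.0], fresh_mg=[1.0])
        with pytest.raises(EvaluationError, match="outside"):
            match_predictions(default_result, obs, "fresh")


class TestSensitivityCoefficient:
    def test_linear_case_is_ten_percent(self):
        # W = c*P: +10% in P gives +10% in W
        assert sensitivity_coefficient(1000.0, 1100.0, 0.10) == pytest.approx(
            10.0)

    def test_insensitive_parameter_is_zero(self):
        assert sensitivity_coefficient(1000.0, 1000.0, 0.10) == 0.0

    def test_frozen_example(self):
        assert sensitivity_coefficient(1000.0, 1050.0, 0.10) == pytest.approx(
            5.0)


class TestSensitivityAnalysis:
    def test_empty_parameter_list(self, default_config):
        table = sensitivity_analysis(default_config, parameters=[])
        assert len(table) == 0

    def test_covers_the_thirteen_calibrated_parameters(self, default_config):
        table = sensitivity_analysis(default_config)
        assert sorted(table["parameter"]) == sorted(CALIBRATED)
        assert set(table["category"]) == set(SENSITIVITY_CATEGORIES.values())
        assert (table["error"] == "").all()

    def test_linear_and_disconnected_parameters_exact(self, params):
        """In a zero-flux configuration the final dry mass equals s_0, so s_0
        is exactly linear and a transport parameter has no pathway at all."""
        frozen = params.with_values(
            v_m=0.0, p_s=0.0, q_m_ref=0.0, q_r=0.0, q_g=0.0,
            L_max=0.0, rho_min=0.0, rho_0=0.0)
        config = SimulationConfig(params=frozen, duration_days=2.0)
        table = sensitivity_analysis(config, parameters=["s_0", "k_ABA"])
        by_name = table.set_index("parameter")
        assert by_name.loc["s_0", "S_dry"] == pytest.approx(10.0, abs=1e-9)
        assert by_name.loc["k_ABA", "S_dry"] == 0.0
        assert by_name.loc["k_ABA", "S_water"] == 0.0
        assert by_name.loc["k_ABA", "S_fresh"] == 0.0


class TestCalibration:
    def test_aba_stage_recovers_thermal_time_parameters(self, default_config,
                                                        default_result):
        obs = synthetic_observations(default_result)
        start = default_config.replace(
            params=default_parameters().with_values(ABA_m=9000.0,
                                                    ABA_e=40000.0))
        res = calibrate(CalibrationSpec(stage="aba", seed=7,
                                        max_evaluations=800), obs, start)
        truth = default_parameters()
        assert res.fitted_values["ABA_m"] == pytest.approx(truth["ABA_m"],
                                                           rel=0.02)
        assert res.fitted_values["ABA_e"] == pytest.approx(truth["ABA_e"],
                                                           rel=0.02)
        # noise-free objective collapses to ~0 relative to the data scale
        assert res.objective_value < 1e-6 * np.max(obs.aba_ug_per_g)

    def test_bounds_excluding_truth_flagged(self, default_config,
                                            default_result):
        obs = synthetic_observations(default_result)
        spec = CalibrationSpec(stage="aba", seed=3, max_evaluations=400,
                               bounds={"ABA_e": (30000.0, 60000.0)})
        res = calibrate(spec, obs, default_config)
        assert res.at_bounds["ABA_e"]

    def test_too_few_observations_rejected(self, default_config):
        obs = ObservationSeries(daa=[10.0, 20.0, 30.0],
                                fresh_mg=[1.0, 2.0, 3.0])
        with pytest.raises(EvaluationError, match=">= 4"):
            calibrate(CalibrationSpec(stage="full"), obs, default_config)
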