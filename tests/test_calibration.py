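"""Smoothing-spline calibration, prediction and cut-point inversion."""

import warnings

import numpy as np
import pytest

from accmet.calibration import (
    CalibrationModel,
    derive_cutpoints,
    fit_smoothing_spline,
    laboratory_calibration_pairs,
    predict_ee,
)
from accmet.energy_expenditure import ActivityBout, METSeries
from accmet.smoothing import normalized_lambda, smoothing_spline


@pytest.fixture
def noisy_linear(rng):
    x = np.sort(rng.uniform(0, 1500, 40))
    y = 1.0 + 0.004 * x + rng.normal(0, 0.3, 40)
    return x, y


class TestSmoothingSplineFit:
    def test_p_zero_equals_least_squares_line(self, noisy_linear):
        x, y = noisy_linear
        model = fit_smoothing_spline(x, y, 0.0)
        slope, intercept = np.polyfit(x, y, 1)
        probe = np.linspace(x[0], x[-1], 17)
        np.testing.assert_allclose(model.predict(probe), intercept + slope * probe, atol=1e-6)

    def test_p_one_interpolates_training_points(self, noisy_linear):
        x, y = noisy_linear
        model = fit_smoothing_spline(x, y, 1.0)
        np.testing.assert_allclose(model.predict(x), y, atol=1e-8)
        assert model.r_squared == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.0, 0.2, 0.9, 1.0])
    def test_exactly_linear_data_reproduced_for_any_p(self, p):
        x = np.linspace(0, 1000, 25)
        y = 1.0 + 0.004 * x
        model = fit_smoothing_spline(x, y, p)
        np.testing.assert_allclose(model.predict(x), y, atol=1e-8)
        assert model.r_squared == pytest.approx(1.0)

    def test_matches_independent_penalized_solver(self, noisy_linear):
        """Same lambda, same answer as scipy's independent implementation."""
        from scipy.interpolate import make_smoothing_spline

        x, y = noisy_linear
        lam = normalized_lambda(0.2, x)
        mine = smoothing_spline(x, y, lam)
        ref = make_smoothing_spline(x, y, lam=lam)
        grid = np.linspace(x[0], x[-1], 200)
        np.testing.assert_allclose(mine(grid), ref(grid), atol=1e-9)

    def test_replicate_sites_equal_weighted_fit(self, rng):
        """Duplicate x values are merged without changing the objective."""
        x = np.array([0.0, 100.0, 100.0, 300.0, 600.0, 900.0])
        y = np.array([1.0, 1.5, 1.7, 2.2, 3.4, 4.6])
        model = fit_smoothing_spline(x, y, 0.2)
        # same fit from pre-averaged site with weight 2
        xu = np.array([0.0, 100.0, 300.0, 600.0, 900.0])
        yu = np.array([1.0, 1.6, 2.2, 3.4, 4.6])
        lam = normalized_lambda(0.2, xu)
        ref = smoothing_spline(xu, yu, lam, w=np.array([1.0, 2.0, 1.0, 1.0, 1.0]))
        grid = np.linspace(0, 900, 50)
        np.testing.assert_allclose(model.predict(grid), ref(grid), atol=1e-10)

    def test_r2_equals_squared_pearson_in_linear_limit(self, noisy_linear):
        x, y = noisy_linear
        model = fit_smoothing_spline(x, y, 0.0)
        r = np.corrcoef(x, y)[0, 1]
        assert model.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_too_few_distinct_sites_rejected(self):
        x = np.array([1.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 1.1, 2.0, 3.0])
        with pytest.raises(ValueError, match="distinct"):
            fit_smoothing_spline(x, y, 0.2)

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fit_smoothing_spline(np.array([0, 1, 2, np.nan]), np.arange(4.0), 0.2)


class TestPredict:
    def test_out_of_range_clamped_to_endpoints(self, noisy_linear):
        x, y = noisy_linear
        model = fit_smoothing_spline(x, y, 0.2)
        with pytest.warns(UserWarning, match="clamped"):
            hi = model.predict(np.array([x[-1] + 500.0]))
        assert hi[0] == pytest.approx(model.predict(np.array([x[-1]]))[0])

    def test_negative_predictions_floored_with_warning(self):
        x = np.array([0.0, 100.0, 200.0, 300.0])
        y = np.array([-2.0, -1.0, 0.5, 1.5])  # line dips below zero
        model = fit_smoothing_spline(x, y, 0.0)
        with pytest.warns(UserWarning, match="floored"):
            out = model.predict(np.array([0.0]))
        assert out[0] == 0.0

    def test_predict_ee_indexes_by_epoch_start(self, intensity_factory, noisy_linear):
        x, y = noisy_linear
        model = fit_smoothing_spline(x, y, 0.2)
        series = intensity_factory([100.0, 500.0, 900.0])
        est = predict_ee(model, series)
        np.testing.assert_array_equal(est.index, [0.0, 60.0, 120.0])
        np.testing.assert_allclose(est.to_numpy(), model.predict(series.intensity))

    def test_serialization_round_trip_is_bit_identical(self, tmp_path, noisy_linear):
        x, y = noisy_linear
        model = fit_smoothing_spline(x, y, 0.2, position="hip")
        path = tmp_path / "model.json"
        model.to_json(path)
        clone = CalibrationModel.from_json(path)
        probe = np.linspace(x[0], x[-1], 1000)
        np.testing.assert_array_equal(model.predict(probe), clone.predict(probe))
        assert clone.smoothing_param == model.smoothing_param
        assert clone.r_squared == model.r_squared


class TestCutPoints:
    def test_linear_model_inverts_analytically(self):
        x = np.linspace(0, 1000, 30)
        model = fit_smoothing_spline(x, 1.0 + 0.004 * x, 0.2)
        cp = derive_cutpoints(model, (3.0,))
        assert cp.cutpoints[3.0] == pytest.approx(500.0, rel=0.01)

    def test_threshold_below_curve_is_undefined(self):
        x = np.linspace(0, 1000, 30)
        model = fit_smoothing_spline(x, 2.0 + 0.004 * x, 0.2)  # min f = 2
        cp = derive_cutpoints(model, (0.5,))
        assert cp.cutpoints[0.5] is None
        assert cp.status[0.5] == "below_calibrated_range"

    def test_threshold_above_curve_is_undefined(self):
        x = np.linspace(0, 500, 30)
        model = fit_smoothing_spline(x, 1.0 + 0.004 * x, 0.2)  # max f = 3
        cp = derive_cutpoints(model, (6.0, 9.0))
        assert cp.cutpoints[6.0] is None and cp.cutpoints[9.0] is None
        assert cp.status[6.0] == "above_calibrated_range"

    def test_smallest_crossing_wins_on_non_monotone_curve(self, rng):
        """Wiggly interpolating spline: first crossing matches a dense scan."""
        x = np.arange(0.0, 400.0, 25.0)
        y = 2.0 + np.sin(x / 40.0)  # oscillates through 2.5 repeatedly
        model = fit_smoothing_spline(x, y, 1.0)
        cp = derive_cutpoints(model, (2.5,))
        grid = np.arange(x[0], x[-1], 0.1)
        vals = model.predict(grid)
        first = grid[np.nonzero(np.diff(np.sign(vals - 2.5)))[0][0]]
        assert cp.cutpoints[2.5] == pytest.approx(first, abs=0.1)

    def test_round_trip_and_monotonicity(self, rng):
        """f(cutpoint(T)) = T and cut-points increase with threshold."""
        for _ in range(10):
            x = np.sort(rng.uniform(0, 2000, 25))
            slope = rng.uniform(0.002, 0.008)
            y = 1.0 + slope * x + rng.normal(0, 0.1, x.size)
            model = fit_smoothing_spline(x, y, 0.2)
            cp = derive_cutpoints(model)
            defined = [(t, v) for t, v in cp.cutpoints.items() if v is not None]
            for t, v in defined:
                assert model._evaluate(np.array([v]))[0] == pytest.approx(t, abs=1e-6)
            values = [v for _, v in sorted(defined)]
            assert values == sorted(values)


class TestLaboratoryPairs:
    def test_one_pair_per_bout_from_steady_state_window(self, intensity_factory):
        mets = METSeries("p1", 60.0 * np.arange(8), np.array([1, 1, 1, 1, 3, 3, 4, 4.0]))
        intensity = intensity_factory([10, 10, 10, 12, 300, 300, 300, 310.0])
        bouts = [ActivityBout("sit", 0.0, 240.0), ActivityBout("slow_walk", 240.0, 480.0)]
        x, y = laboratory_calibration_pairs(intensity, mets, bouts)
        np.testing.assert_allclose(x, [12.0, 310.0])
        np.testing.assert_allclose(y, [1.0, 4.0])

    def test_missing_window_epochs_rejected(self, intensity_factory):
        mets = METSeries("p1", 60.0 * np.arange(4), np.full(4, 2.0))
        intensity = intensity_factory([10.0, 10.0], epoch_length=60.0)  # only 2 min
        with pytest.raises(ValueError, match="no intensity epochs"):
            laboratory_calibration_pairs(
                intensity, mets, [ActivityBout("sit", 0.0, 240.0)]
            )
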