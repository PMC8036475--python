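"""Temporal alignment, agreement statistics and leave-one-out validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from accmet.energy_expenditure import METSeries
from accmet.validation import (
    agreement,
    align_minutes,
    free_living_calibration_pairs,
    loo_cross_validate,
    participant_means,
)


def _series(values, start=0.0):
    values = np.asarray(values, dtype=float)
    return pd.Series(values, index=start + 60.0 * np.arange(values.size))


class TestAlignMinutes:
    def test_two_minute_overlap_rule(self):
        pairs = align_minutes(_series([2, 4, 6]), _series([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(pairs["estimated_met"], [3.0, 5.0])
        np.testing.assert_allclose(pairs["measured_met"], [2.0, 3.0])
        np.testing.assert_allclose(pairs["minute_start"], [60.0, 120.0])

    def test_constant_estimate_stays_constant(self):
        pairs = align_minutes(_series([3, 3, 3, 3]), _series([1, 2, 3, 4]))
        np.testing.assert_allclose(pairs["estimated_met"], 3.0)

    def test_gap_unpairs_following_minute(self):
        est = pd.Series([2.0, 6.0, 8.0], index=[0.0, 120.0, 180.0])  # minute 1 missing
        meas = _series([1, 1, 1, 1.0])
        pairs = align_minutes(est, meas)
        # minute 2 lacks t-1; only minute 3 has a complete window
        np.testing.assert_allclose(pairs["minute_start"], [180.0])
        np.testing.assert_allclose(pairs["estimated_met"], [7.0])

    def test_output_length_for_gap_free_series(self):
        n = 10
        pairs = align_minutes(_series(np.arange(n) + 1.0), _series(np.ones(n)))
        assert len(pairs) == n - 1

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="no overlapping"):
            align_minutes(_series([1, 2]), _series([1, 2], start=600.0))

    def test_accepts_met_series_input(self):
        meas = METSeries("p1", 60.0 * np.arange(3), np.array([1.0, 2.0, 3.0]))
        pairs = align_minutes(_series([2, 4, 6]), meas, participant_id="p1")
        assert (pairs["participant_id"] == "p1").all()


class TestParticipantMeans:
    def test_single_participant_mean(self):
        pairs = pd.DataFrame(
            {
                "participant_id": ["a", "a"],
                "minute_start": [60.0, 120.0],
                "estimated_met": [3.0, 5.0],
                "measured_met": [2.0, 4.0],
            }
        )
        means = participant_means(pairs)
        assert means.loc[0, "estimated_met"] == pytest.approx(4.0)
        assert means.loc[0, "measured_met"] == pytest.approx(3.0)

    def test_one_row_per_participant(self):
        pairs = pd.DataFrame(
            {
                "participant_id": ["a", "a", "b"],
                "minute_start": [60.0, 120.0, 60.0],
                "estimated_met": [1.0, 2.0, 3.0],
                "measured_met": [1.0, 2.0, 3.0],
            }
        )
        assert len(participant_means(pairs)) == 2


class TestAgreement:
    def test_perfect_agreement(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        s = agreement(v, v, n_boot=0)
        assert s.pearson_r == pytest.approx(1.0)
        assert s.rmse == 0.0
        assert s.mean_bias == 0.0
        assert s.loa_low == 0.0 and s.loa_high == 0.0

    def test_constant_offset(self):
        v = np.array([1.0, 2.0, 3.0])
        s = agreement(v + 0.5, v, n_boot=0)
        assert s.rmse == pytest.approx(0.5)
        assert s.mean_bias == pytest.approx(0.5)
        assert s.pearson_r == pytest.approx(1.0)

    def test_hand_computed_three_point_case(self):
        s = agreement(np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0]), n_boot=0)
        assert s.pearson_r == pytest.approx(-1.0)
        assert s.rmse == pytest.approx(np.sqrt(8.0 / 3.0))

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            s = agreement(np.array([2.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0]), n_boot=0)
        assert np.isnan(s.pearson_r)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        est=arrays(np.float64, 8, elements=st.floats(0.5, 12.0)),
        meas=arrays(np.float64, 8, elements=st.floats(0.5, 12.0)),
    )
    def test_metric_identities(self, est, meas):
        """rmse^2 = bias^2 + ((n-1)/n) var(diff); LoA = bias +/- 2 SD."""
        s = agreement(est, meas, n_boot=0)
        diff = est - meas
        n = diff.size
        var = diff.var(ddof=1)
        assert s.rmse**2 == pytest.approx(s.mean_bias**2 + (n - 1) / n * var, abs=1e-12)
        sd = np.sqrt(var)
        assert s.loa_low == pytest.approx(s.mean_bias - 2 * sd, abs=1e-12)
        assert s.loa_high == pytest.approx(s.mean_bias + 2 * sd, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        est=arrays(np.float64, 6, elements=st.floats(0.5, 12.0)),
        meas=arrays(np.float64, 6, elements=st.floats(0.5, 12.0)),
    )
    def test_swap_symmetry(self, est, meas):
        """Swapping series: r unchanged, bias flips sign, rmse unchanged."""
        a = agreement(est, meas, n_boot=0)
        b = agreement(meas, est, n_boot=0)
        if not (np.isnan(a.pearson_r) and np.isnan(b.pearson_r)):
            assert a.pearson_r == pytest.approx(b.pearson_r, abs=1e-12)
        assert a.mean_bias == pytest.approx(-b.mean_bias, abs=1e-12)
        assert a.rmse == pytest.approx(b.rmse, abs=1e-12)

    def test_bootstrap_ci_deterministic_given_seed(self, rng):
        est = rng.uniform(1, 5, 40)
        meas = est + rng.normal(0, 0.5, 40)
        a = agreement(est, meas, n_boot=200, seed=7)
        b = agreement(est, meas, n_boot=200, seed=7)
        assert a.ci["rmse"] == b.ci["rmse"]
        lo, hi = a.ci["rmse"]
        assert lo <= a.rmse <= hi


def _loo_dataset(rng, n_participants=5, n_minutes=30, noise=0.0):
    frames = []
    for k in range(n_participants):
        x = rng.uniform(0, 600, n_minutes)
        y = 1.0 + 0.004 * x + (rng.normal(0, noise, n_minutes) if noise else 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": f"p{k}",
                    "minute_start": 60.0 * (1 + np.arange(n_minutes)),
                    "intensity": x,
                    "measured_met": y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestLeaveOneOut:
    def test_each_participant_predicted_exactly_once(self, rng):
        data = _loo_dataset(rng, n_participants=5, noise=0.2)
        res = loo_cross_validate(data, n_boot=0)
        assert res.n_folds == 5
        counts = res.predictions.groupby("participant_id").size()
        assert (counts == 30).all()
        assert len(res.predictions) == len(data)

    def test_noise_free_linear_truth_recovered(self, rng):
        # exact up to range clamping: a held-out minute beyond a fold's
        # training range gets the endpoint prediction, not the true line
        data = _loo_dataset(rng, noise=0.0)
        res = loo_cross_validate(data, n_boot=0)
        assert res.minute.pearson_r > 0.999
        assert res.minute.rmse < 0.02
        assert res.subject_mean.rmse < 0.02

    def test_too_few_participants_rejected(self, rng):
        data = _loo_dataset(rng, n_participants=2, noise=0.1)
        with pytest.raises(ValueError, match="at least 3"):
            loo_cross_validate(data, n_boot=0)

    def test_degenerate_fold_named_in_error(self):
        # participant 'bad' holds all x variation; leaving others out is fine,
        # but the fold excluding 'bad' has a single distinct training site
        frames = []
        for pid, xs in [("bad", [0, 200, 400, 600]), ("a", [100] * 4), ("b", [100] * 4)]:
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "minute_start": 60.0 * np.arange(1, 5),
                        "intensity": np.array(xs, dtype=float),
                        "measured_met": np.full(4, 2.0),
                    }
                )
            )
        with pytest.raises(ValueError, match="leaving out 'bad'"):
            loo_cross_validate(pd.concat(frames, ignore_index=True), n_boot=0)


class TestFreeLivingPairs:
    def test_intensity_gets_same_overlap_alignment(self, intensity_factory):
        intensity = intensity_factory([100.0, 200.0, 300.0])
        meas = _series([1.5, 2.0, 2.5])
        pairs = free_living_calibration_pairs(intensity, meas, "p1")
        np.testing.assert_allclose(pairs["intensity"], [150.0, 250.0])
        np.testing.assert_allclose(pairs["measured_met"], [2.0, 2.5])
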