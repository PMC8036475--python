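"""Agreement between estimated and measured energy expenditure.

Measured EE (indirect calorimetry) responds to mechanical work with a
lag of tens of seconds, so minute-by-minute comparison uses a temporal
alignment rule: each one-minute mean of *measured* EE is compared with
the two-minute mean of the *estimate* over the same and the previous
minute (two-minute windows with 50% overlap).  Agreement is summarized
by Pearson r, RMSE and Bland-Altman statistics (mean bias and limits of
agreement at +/- 2 SD of the differences), at minute resolution and at
participant-mean resolution.  Free-living calibrations are assessed by
leave-one-participant-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationModel, fit_smoothing_spline
from .energy_expenditure import METSeries, MINUTE
from .signal_processing import IntensitySeries

__all__ = [
    "AgreementStats",
    "LOOResult",
    "align_minutes",
    "free_living_calibration_pairs",
    "participant_means",
    "agreement",
    "loo_cross_validate",
]


@dataclass
class AgreementStats:
    """Agreement summary for estimated vs measured EE (METs).

    ``pearson_r`` is NaN (flagged by a warning) when either series has
    zero variance.  ``ci`` maps statistic name -> (low, high): Fisher-z
    interval for r, seeded nonparametric bootstrap for rmse and bias
    (resampling participants, or minutes clustered by participant, when
    cluster labels are supplied).
    """

    pearson_r: float
    rmse: float
    mean_bias: float
    loa_low: float
    loa_high: float
    n: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "pearson_r": self.pearson_r,
            "rmse": self.rmse,
            "mean_bias": self.mean_bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
        }
        d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def _to_minute_series(series: METSeries | pd.Series) -> pd.Series:
    if isinstance(series, METSeries):
        return pd.Series(series.mets, index=series.minute_start)
    return series


def _overlap_align(values: pd.Series, measured: pd.Series) -> pd.DataFrame:
    """Two-minute 50%-overlap alignment of per-minute values to measured EE.

    For each minute t present in ``measured`` where ``values`` holds both
    t and t-1, pairs mean(values[t-1], values[t]) with measured[t].  The
    first minute can never be paired (no previous minute exists), and a
    gap in ``values`` unpairs the following minute as well.
    """
    prev = values.copy()
    prev.index = prev.index + MINUTE
    window = (values + prev) / 2.0  # NaN wherever t or t-1 is missing
    df = pd.DataFrame({"value": window, "measured": measured}).dropna()
    if df.empty:
        raise ValueError("no overlapping minutes between the two series")
    df.index.name = "minute_start"
    return df.reset_index()


def align_minutes(
    estimated: pd.Series, measured: METSeries | pd.Series, participant_id: str = ""
) -> pd.DataFrame:
    """Pair two-minute-mean estimated EE with one-minute measured EE.

    Returns a PairedMinutes frame with columns ``participant_id``,
    ``minute_start``, ``estimated_met``, ``measured_met``.
    """
    df = _overlap_align(estimated, _to_minute_series(measured))
    df = df.rename(columns={"value": "estimated_met", "measured": "measured_met"})
    df.insert(0, "participant_id", participant_id)
    return df


def free_living_calibration_pairs(
    intensity: IntensitySeries, measured: METSeries | pd.Series, participant_id: str = ""
) -> pd.DataFrame:
    """Minute-level (intensity, measured MET) pairs for free-living calibration.

    The same two-minute 50%-overlap rule used for validation is applied
    on the intensity side, so the calibration is fitted on exactly the
    alignment at which it will be evaluated.
    """
    intensity_series = pd.Series(intensity.intensity, index=intensity.epoch_start)
    df = _overlap_align(intensity_series, _to_minute_series(measured))
    df = df.rename(columns={"value": "intensity", "measured": "measured_met"})
    df.insert(0, "participant_id", participant_id)
    return df


def participant_means(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean estimated and measured EE over the session."""
    if pairs.empty:
        raise ValueError("no paired minutes")
    return (
        pairs.groupby("participant_id")[["estimated_met", "measured_met"]]
        .mean()
        .reset_index()
    )


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n < 4 or not np.isfinite(r) or abs(r) >= 1:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def agreement(
    estimated: np.ndarray,
    measured: np.ndarray,
    *,
    clusters: np.ndarray | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementStats:
    """Pearson r, RMSE and Bland-Altman statistics for paired EE values.

    Limits of agreement use bias +/- 2 * SD of the differences (sample
    SD).  Bootstrap CIs for rmse and bias resample whole clusters
    (participants) when ``clusters`` is given, otherwise individual
    pairs; ``n_boot = 0`` skips bootstrap CIs.
    """
    est = np.asarray(estimated, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if est.size != meas.size:
        raise ValueError("estimated and measured must have equal length")
    n = est.size
    if n < 3:
        raise ValueError("need at least 3 pairs")

    diff = est - meas
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    rmse = float(np.sqrt(np.mean(diff**2)))
    if est.std() == 0 or meas.std() == 0:
        warnings.warn("zero variance in a series: Pearson r undefined", stacklevel=2)
        r = np.nan
    else:
        r = float(stats.pearsonr(est, meas).statistic)

    ci: dict[str, tuple[float, float]] = {"pearson_r": _fisher_ci(r, n)}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        if clusters is not None:
            labels = np.asarray(clusters)
            uniq = np.unique(labels)
            groups = [np.nonzero(labels == u)[0] for u in uniq]
            idx_sets = (
                np.concatenate([groups[g] for g in rng.integers(0, len(groups), len(groups))])
                for _ in range(n_boot)
            )
        else:
            idx_sets = (rng.integers(0, n, n) for _ in range(n_boot))
        boot_rmse = np.empty(n_boot)
        boot_bias = np.empty(n_boot)
        for k, idx in enumerate(idx_sets):
            d = diff[idx]
            boot_rmse[k] = np.sqrt(np.mean(d**2))
            boot_bias[k] = d.mean()
        ci["rmse"] = tuple(np.percentile(boot_rmse, [2.5, 97.5]))
        ci["mean_bias"] = tuple(np.percentile(boot_bias, [2.5, 97.5]))

    return AgreementStats(
        pearson_r=r,
        rmse=rmse,
        mean_bias=bias,
        loa_low=bias - 2 * sd,
        loa_high=bias + 2 * sd,
        n=n,
        ci=ci,
    )


def agreement_from_pairs(
    pairs: pd.DataFrame, *, cluster_by_participant: bool = True, n_boot: int = 2000, seed: int = 0
) -> AgreementStats:
    """Convenience wrapper running :func:`agreement` on a PairedMinutes frame."""
    clusters = pairs["participant_id"].to_numpy() if cluster_by_participant else None
    return agreement(
        pairs["estimated_met"].to_numpy(),
        pairs["measured_met"].to_numpy(),
        clusters=clusters,
        n_boot=n_boot,
        seed=seed,
    )


@dataclass
class LOOResult:
    """Pooled leave-one-participant-out validation results."""

    minute: AgreementStats
    subject_mean: AgreementStats
    n_folds: int
    predictions: pd.DataFrame  # pooled PairedMinutes across folds


def loo_cross_validate(
    pairs: pd.DataFrame,
    smoothing_param: float = 0.2,
    *,
    position: str = "",
    n_boot: int = 2000,
    seed: int = 0,
) -> LOOResult:
    """Leave-one-participant-out validation of free-living calibration.

    ``pairs`` holds minute-level columns ``participant_id``,
    ``intensity`` (mg, already on the validation alignment) and
    ``measured_met``.  Each fold fits the smoothing-spline calibration on
    all other participants' minutes and predicts the held-out
    participant; predictions from all folds are pooled into a single
    agreement statistic at minute and at participant-mean resolution.
    """
    participants = pairs["participant_id"].unique()
    if len(participants) < 3:
        raise ValueError("leave-one-out needs at least 3 participants")

    pooled = []
    for pid in participants:
        train = pairs[pairs["participant_id"] != pid]
        test = pairs[pairs["participant_id"] == pid]
        try:
            model = fit_smoothing_spline(
                train["intensity"].to_numpy(),
                train["measured_met"].to_numpy(),
                smoothing_param,
                position=position,
                source="free_living",
            )
        except ValueError as err:
            raise ValueError(f"fold leaving out {pid!r}: {err}") from err
        # silent clamp + floor: out-of-range test minutes are expected in LOO
        est = np.maximum(model._evaluate(test["intensity"].to_numpy()), 0.0)
        pooled.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "minute_start": test["minute_start"].to_numpy(),
                    "estimated_met": est,
                    "measured_met": test["measured_met"].to_numpy(),
                }
            )
        )
    predictions = pd.concat(pooled, ignore_index=True)

    minute_stats = agreement_from_pairs(predictions, n_boot=n_boot, seed=seed)
    means = participant_means(predictions)
    subject_stats = agreement(
        means["estimated_met"].to_numpy(),
        means["measured_met"].to_numpy(),
        n_boot=n_boot,
        seed=seed,
    )
    return LOOResult(
        minute=minute_stats,
        subject_mean=subject_stats,
        n_folds=len(participants),
        predictions=predictions,
    )
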