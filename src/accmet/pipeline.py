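"""Cohort-level orchestration of the calibration/validation pipeline.

These helpers run the full chain on a list of participants (in-memory
:class:`~accmet.synthetic.ParticipantData` or data loaded from disk):
raw signals -> epoch intensity -> minute METs -> calibration models ->
cut-points -> agreement statistics and leave-one-out validation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationModel,
    fit_smoothing_spline,
    laboratory_calibration_pairs,
    predict_ee,
)
from .energy_expenditure import METSeries, compute_mets
from .signal_processing import FilterSpec, IntensitySeries, process_recording
from .synthetic import ParticipantData, STUDY_POSITIONS
from .validation import (
    AgreementStats,
    LOOResult,
    agreement,
    agreement_from_pairs,
    align_minutes,
    free_living_calibration_pairs,
    loo_cross_validate,
    participant_means,
)
from .workload import SegmentWeightTable, full_body_workload

__all__ = [
    "process_cohort",
    "measured_cohort",
    "pooled_laboratory_pairs",
    "pooled_free_living_pairs",
    "calibrate_cohort",
    "validate_cohort",
    "loo_validate_cohort",
    "cohort_workload_r2",
]

IntensityMap = dict[str, dict[str, IntensitySeries]]  # pid -> position -> series


def process_cohort(
    parts: list[ParticipantData],
    positions: tuple[str, ...] = STUDY_POSITIONS,
    spec: FilterSpec | None = None,
    epoch_length: float = 60.0,
) -> IntensityMap:
    """Band-pass + vector magnitude + epoch aggregation for each stream."""
    out: IntensityMap = {}
    for part in parts:
        out[part.participant_id] = {
            pos: process_recording(part.recordings[pos], spec, epoch_length)
            for pos in positions
        }
    return out


def measured_cohort(parts: list[ParticipantData]) -> dict[str, METSeries]:
    """Minute-resolved measured METs per participant."""
    return {p.participant_id: compute_mets(p.breaths) for p in parts}


def pooled_laboratory_pairs(
    parts: list[ParticipantData],
    intensities: IntensityMap,
    measured: dict[str, METSeries],
    position: str,
    window: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One steady-state (intensity, MET) pair per participant x activity."""
    xs, ys = [], []
    for part in parts:
        x, y = laboratory_calibration_pairs(
            intensities[part.participant_id][position],
            measured[part.participant_id],
            part.bouts,
            window=window,
        )
        xs.append(x)
        ys.append(y)
    return np.concatenate(xs), np.concatenate(ys)


def pooled_free_living_pairs(
    parts: list[ParticipantData],
    intensities: IntensityMap,
    measured: dict[str, METSeries],
    position: str,
) -> pd.DataFrame:
    """Pooled minute-level pairs on the two-minute-overlap alignment."""
    frames = [
        free_living_calibration_pairs(
            intensities[p.participant_id][position],
            measured[p.participant_id],
            p.participant_id,
        )
        for p in parts
    ]
    return pd.concat(frames, ignore_index=True)


def calibrate_cohort(
    parts: list[ParticipantData],
    intensities: IntensityMap,
    measured: dict[str, METSeries],
    mode: str,
    positions: tuple[str, ...] = STUDY_POSITIONS,
    smoothing_param: float = 0.2,
) -> dict[str, CalibrationModel]:
    """Fit one calibration model per position from pooled cohort pairs."""
    models = {}
    for pos in positions:
        if mode == "laboratory":
            x, y = pooled_laboratory_pairs(parts, intensities, measured, pos)
        elif mode == "free_living":
            pairs = pooled_free_living_pairs(parts, intensities, measured, pos)
            x = pairs["intensity"].to_numpy()
            y = pairs["measured_met"].to_numpy()
        else:
            raise ValueError(f"unknown calibration mode {mode!r}")
        models[pos] = fit_smoothing_spline(
            x, y, smoothing_param, position=pos, source=mode
        )
    return models


def validate_cohort(
    parts: list[ParticipantData],
    intensities: IntensityMap,
    measured: dict[str, METSeries],
    models: dict[str, CalibrationModel],
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, dict[str, AgreementStats]]:
    """Minute-by-minute and participant-mean agreement per position."""
    report = {}
    for pos, model in models.items():
        frames = []
        for part in parts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # range clamping is expected here
                est = predict_ee(model, intensities[part.participant_id][pos])
            frames.append(
                align_minutes(est, measured[part.participant_id], part.participant_id)
            )
        pairs = pd.concat(frames, ignore_index=True)
        minute_stats = agreement_from_pairs(pairs, n_boot=n_boot, seed=seed)
        means = participant_means(pairs)
        subject_stats = agreement(
            means["estimated_met"].to_numpy(),
            means["measured_met"].to_numpy(),
            n_boot=n_boot,
            seed=seed,
        )
        report[pos] = {"minute": minute_stats, "subject_mean": subject_stats}
    return report


def loo_validate_cohort(
    parts: list[ParticipantData],
    intensities: IntensityMap,
    measured: dict[str, METSeries],
    position: str,
    smoothing_param: float = 0.2,
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> LOOResult:
    """Leave-one-participant-out validation of the free-living calibration."""
    pairs = pooled_free_living_pairs(parts, intensities, measured, position)
    return loo_cross_validate(
        pairs, smoothing_param, position=position, n_boot=n_boot, seed=seed
    )


def cohort_workload_r2(
    parts: list[ParticipantData],
    intensities: IntensityMap,
    position: str,
    weights: SegmentWeightTable | None = None,
    smoothing_param: float = 0.2,
) -> float:
    """R^2 of one sensor against the full-body workload reference.

    The nine segment series of each participant are combined into the
    weighted full-body channel; epochs from all participants are pooled
    before the smoothing-spline fit.
    """
    xs, ys = [], []
    for part in parts:
        imap = intensities[part.participant_id]
        fb = full_body_workload(imap, weights)
        single = imap[position]
        common, i_s, i_f = np.intersect1d(
            np.round(single.epoch_start, 6),
            np.round(fb.epoch_start, 6),
            return_indices=True,
        )
        xs.append(single.intensity[i_s])
        ys.append(fb.intensity[i_f])
    fit = fit_smoothing_spline(
        np.concatenate(xs),
        np.concatenate(ys),
        smoothing_param,
        position=position,
        source="workload",
    )
    return fit.r_squared
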