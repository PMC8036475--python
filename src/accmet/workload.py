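"""Segment-mass-weighted full-body mechanical workload reference.

Nine body-segment accelerometers (shanks, thighs, forearms, upper arms,
trunk including head) are processed with the same band-pass chain as the
study positions; each segment's intensity is weighted by the segment's
approximate mass fraction of total body mass and summed, giving a
single-channel reference for whole-body mechanical work.  Feet and hands
carry no sensor, so the fractions sum to slightly less than 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibration import CalibrationModel, fit_smoothing_spline
from .signal_processing import IntensitySeries

__all__ = ["SEGMENTS", "SegmentWeightTable", "full_body_workload", "workload_association"]

SEGMENTS = (
    "shank_L",
    "shank_R",
    "thigh_L",
    "thigh_R",
    "upper_arm_L",
    "upper_arm_R",
    "forearm_L",
    "forearm_R",
    "trunk",
)

# Standard anthropometric mass fractions of total body mass (head and neck
# lumped into the trunk; feet and hands excluded as they carry no sensor).
_DEFAULT_FRACTIONS = {
    "shank_L": 0.0465,
    "shank_R": 0.0465,
    "thigh_L": 0.100,
    "thigh_R": 0.100,
    "upper_arm_L": 0.028,
    "upper_arm_R": 0.028,
    "forearm_L": 0.016,
    "forearm_R": 0.016,
    "trunk": 0.578,
}


@dataclass(frozen=True)
class SegmentWeightTable:
    """Segment -> mass-fraction mapping; user-overridable."""

    fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )

    def __post_init__(self) -> None:
        missing = [s for s in SEGMENTS if s not in self.fractions]
        if missing:
            raise ValueError(f"missing segment fractions: {missing}")
        for seg, f in self.fractions.items():
            if not 0 < f < 1:
                raise ValueError(f"fraction for {seg!r} must be in (0, 1)")
        if sum(self.fractions[s] for s in SEGMENTS) > 1 + 1e-9:
            raise ValueError("segment fractions must sum to at most 1")

    def __getitem__(self, segment: str) -> float:
        return self.fractions[segment]


def full_body_workload(
    series: Mapping[str, IntensitySeries],
    weights: SegmentWeightTable | None = None,
) -> IntensitySeries:
    """Epoch-wise weighted sum of the nine segment intensity series.

    All nine segments must be present on a common epoch grid; an epoch
    missing from any segment is excluded from the output.
    """
    weights = weights or SegmentWeightTable()
    missing = [s for s in SEGMENTS if s not in series]
    if missing:
        raise ValueError(f"missing segment series: {missing}")

    first = series[SEGMENTS[0]]
    for seg in SEGMENTS[1:]:
        if series[seg].epoch_length != first.epoch_length:
            raise ValueError(
                f"segment {seg!r} uses epoch length {series[seg].epoch_length}, "
                f"expected {first.epoch_length}"
            )

    common = set(np.round(first.epoch_start, 6))
    for seg in SEGMENTS[1:]:
        common &= set(np.round(series[seg].epoch_start, 6))
    if not common:
        raise ValueError("segment series share no epochs")
    starts = np.array(sorted(common))

    total = np.zeros(starts.size)
    for seg in SEGMENTS:
        s = series[seg]
        lookup = dict(zip(np.round(s.epoch_start, 6), s.intensity))
        total += weights[seg] * np.array([lookup[t] for t in starts])

    return IntensitySeries(
        participant_id=first.participant_id,
        position="full_body",
        epoch_start=starts,
        epoch_length=first.epoch_length,
        intensity=total,
    )


def workload_association(
    single: IntensitySeries,
    full_body: IntensitySeries,
    smoothing_param: float = 0.2,
) -> tuple[CalibrationModel, float]:
    """Smoothing-spline association of one sensor with full-body workload.

    Fits full-body intensity as a spline function of the single sensor's
    intensity over their shared epochs and returns the fit with its R^2,
    quantifying how representative the single position is of whole-body
    mechanical work.
    """
    if single.epoch_length != full_body.epoch_length:
        raise ValueError("series use different epoch lengths")
    common, i_single, i_full = np.intersect1d(
        np.round(single.epoch_start, 6),
        np.round(full_body.epoch_start, 6),
        return_indices=True,
    )
    if common.size == 0:
        raise ValueError("series share no epochs")
    fit = fit_smoothing_spline(
        single.intensity[i_single],
        full_body.intensity[i_full],
        smoothing_param,
        position=single.position,
        source="workload",
    )
    return fit, fit.r_squared
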