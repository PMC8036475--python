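"""Breath-by-breath oxygen uptake to minute-resolved METs.

Energy expenditure is expressed in metabolic equivalents (METs): oxygen
consumption relative to an estimated resting metabolic rate of
3.5 mL O2 per minute per kg of body mass.  Breath-level VO2 is averaged
within clock minutes (unweighted mean over breaths) and divided by the
resting reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RESTING_VO2_PER_KG",
    "ACTIVITIES",
    "BreathSeries",
    "METSeries",
    "ActivityBout",
    "compute_mets",
    "steady_state_met",
]

#: Estimated resting metabolic rate, mL O2 . min^-1 . kg^-1.
RESTING_VO2_PER_KG = 3.5

#: Laboratory protocol activities, in protocol order.
ACTIVITIES = ("sit", "stand", "slow_walk", "brisk_walk", "run")

#: Laboratory bout duration in seconds (four minutes to reach VO2 steady state).
BOUT_SECONDS = 240.0

MINUTE = 60.0


@dataclass
class BreathSeries:
    """Breath-by-breath oxygen consumption for one participant.

    ``breath_time`` is in seconds on the session clock, strictly
    increasing; ``vo2`` is per-breath oxygen uptake in mL/min.
    """

    participant_id: str
    breath_time: np.ndarray
    vo2: np.ndarray
    body_mass: float

    def __post_init__(self) -> None:
        self.breath_time = np.asarray(self.breath_time, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if len(self.breath_time) != len(self.vo2):
            raise ValueError("breath_time and vo2 must have equal length")
        if np.any(self.vo2 <= 0):
            raise ValueError("vo2 must be positive")
        if len(self.breath_time) > 1 and np.any(np.diff(self.breath_time) <= 0):
            raise ValueError("breath_time must be strictly increasing")


@dataclass
class METSeries:
    """Minute-resolved energy expenditure in METs.

    ``minute_start`` is in seconds; each value covers the half-open
    minute ``[minute_start, minute_start + 60)``.  Minutes are strictly
    increasing but may have gaps (minutes without breaths are absent).
    """

    participant_id: str
    minute_start: np.ndarray
    mets: np.ndarray

    def __post_init__(self) -> None:
        self.minute_start = np.asarray(self.minute_start, dtype=float)
        self.mets = np.asarray(self.mets, dtype=float)
        if len(self.minute_start) != len(self.mets):
            raise ValueError("minute_start and mets must have equal length")
        if np.any(self.mets <= 0):
            raise ValueError("mets must be positive")
        if len(self.minute_start) > 1 and np.any(np.diff(self.minute_start) < MINUTE - 1e-9):
            raise ValueError("minutes overlap")

    def __len__(self) -> int:
        return len(self.mets)


@dataclass(frozen=True)
class ActivityBout:
    """A timed activity interval from the laboratory protocol."""

    activity: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.end <= self.start:
            raise ValueError("bout end must be after start")


def compute_mets(
    breaths: BreathSeries, resting_vo2_per_kg: float = RESTING_VO2_PER_KG
) -> METSeries:
    """Convert a breath series to minute-resolved METs.

    Per minute: METs = mean(vo2 over breaths in the minute) /
    (body_mass * resting_vo2_per_kg).  Minutes containing no breath are
    absent from the output.
    """
    if len(breaths.vo2) == 0:
        raise ValueError("empty breath series")
    if resting_vo2_per_kg <= 0:
        raise ValueError("resting_vo2_per_kg must be positive")
    minute_idx = np.floor(breaths.breath_time / MINUTE).astype(int)
    unique_minutes, inverse = np.unique(minute_idx, return_inverse=True)
    sums = np.bincount(inverse, weights=breaths.vo2)
    counts = np.bincount(inverse)
    mets = (sums / counts) / (breaths.body_mass * resting_vo2_per_kg)
    return METSeries(
        participant_id=breaths.participant_id,
        minute_start=unique_minutes * MINUTE,
        mets=mets,
    )


def steady_state_met(mets: METSeries, bout: ActivityBout, window: float = 60.0) -> float:
    """Mean METs over the final ``window`` seconds of an activity bout.

    Four-minute constant-intensity bouts reach a VO2 plateau before the
    end; the default takes the final minute.  Only whole minutes fully
    inside ``[bout.end - window, bout.end)`` contribute.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lo = bout.end - window
    covered = (mets.minute_start >= bout.start - 1e-9) & (
        mets.minute_start + MINUTE <= bout.end + 1e-9
    )
    n_expected = int(round((bout.end - bout.start) / MINUTE))
    if covered.sum() < n_expected:
        raise ValueError(
            f"bout [{bout.start}, {bout.end}) not fully covered by the MET series"
        )
    in_window = covered & (mets.minute_start >= lo - 1e-9)
    return float(mets.mets[in_window].mean())
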