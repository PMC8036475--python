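"""Seeded synthetic accelerometer and calorimetry data with known truth.

The generator emulates the two study conditions end to end so every
pipeline stage is testable without recorded data:

* **laboratory** mode: five 4-minute constant-intensity bouts (sit,
  stand, slow walk, brisk walk, run; Sudoku-style wrist fidgeting during
  the stationary bouts);
* **free_living** mode: ~60-minute workplace sessions whose minutes are
  drawn from a mix dominated by low-intensity activity.

Raw signals are gravity (a slowly rotating unit vector, below the
high-pass corner) plus band-limited stochastic movement whose band-pass
vector-magnitude mean is controlled block-by-block; locomotor activities
add a gait harmonic (1.5-3 Hz).  Ground truth is a monotone intensity ->
MET curve g; VO2 is body_mass * 3.5 * g(intensity) passed through a
first-order lag and sampled breath-by-breath with Gaussian noise.  Wrist
streams receive extra movement during stationary activities that is
independent of EE ("decoupling").  In free-living mode the emitted
movement per MET can be scaled down relative to laboratory
(``free_living_intensity_scale``), reproducing the regime where
laboratory calibrations underestimate free-living EE.

Identical (config, participant index) always yields bit-identical
output; independent random streams are used per purpose so that
restricting ``positions`` does not perturb the schedule or the breaths.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .energy_expenditure import ACTIVITIES, ActivityBout, BreathSeries, METSeries, MINUTE
from .signal_processing import FilterSpec, POSITIONS, TriaxialRecording
from .workload import SEGMENTS

__all__ = [
    "TrueCurve",
    "SimulationConfig",
    "ParticipantData",
    "simulate_participant",
    "simulate_cohort",
    "STUDY_POSITIONS",
]

#: The four positions evaluated for EE estimation.
STUDY_POSITIONS = ("shoe", "hip", "thigh", "wrist")

_LOCOMOTOR = {"slow_walk": 1.6, "brisk_walk": 2.0, "run": 2.7}  # stride Hz
_STATIONARY = ("sit", "stand")
_AXIS_WEIGHTS = np.array([1.0, 0.5, 0.8])  # relative movement per axis


@dataclass(frozen=True)
class TrueCurve:
    """Monotone ground-truth intensity (mg) -> MET relationship.

    ``saturating``: MET = 1 + a*x / (1 + x/b) — concave, levelling off at
    1 + a*b, the shape typical of empirical calibration curves.
    ``linear``: MET = 1 + slope*x, kept for analytic tests.
    """

    kind: str = "saturating"
    a: float = 0.009  # initial slope, METs per mg (saturating)
    b: float = 2000.0  # half-saturation intensity, mg
    slope: float = 0.004  # METs per mg (linear)

    def __post_init__(self) -> None:
        if self.kind not in ("saturating", "linear"):
            raise ValueError(f"unknown curve kind {self.kind!r}")

    def met(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            out = 1.0 + self.slope * x
        else:
            out = 1.0 + self.a * x / (1.0 + x / self.b)
        return out if out.ndim else float(out)

    def intensity_at(self, met: float) -> float:
        """Analytic inverse: intensity at which the curve reaches ``met``."""
        if met <= 1.0:
            raise ValueError("curve starts at 1 MET; no intensity below rest")
        if self.kind == "linear":
            return (met - 1.0) / self.slope
        denom = self.a - (met - 1.0) / self.b
        if denom <= 0:
            raise ValueError(f"curve saturates below {met} METs")
        return (met - 1.0) / denom


def _default_gains() -> dict[str, float]:
    # Position-specific amplitude of movement relative to the full-body
    # reference: impacts grow toward the ground (shoe > thigh > hip).
    return {
        "shoe": 2.0,
        "hip": 1.0,
        "thigh": 1.3,
        "wrist": 0.9,
        "shank_L": 1.6,
        "shank_R": 1.6,
        "thigh_L": 1.3,
        "thigh_R": 1.3,
        "upper_arm_L": 0.7,
        "upper_arm_R": 0.7,
        "forearm_L": 0.9,
        "forearm_R": 0.9,
        "trunk": 0.8,
    }


def _default_mix() -> dict[str, float]:
    # Workplace sessions are dominated by stationary work (~82% of
    # minutes), and no free-living activity reaches the intensity of
    # brisk laboratory walking; slow ambulation is the ceiling.
    return {"sit": 0.45, "stand": 0.37, "slow_walk": 0.18}


def _default_lab_intensity() -> dict[str, float]:
    # Full-body movement intensity (mg) per laboratory activity.
    return {"sit": 10.0, "stand": 18.0, "slow_walk": 300.0, "brisk_walk": 600.0, "run": 1500.0}


def _default_free_intensity() -> dict[str, float]:
    # Workplace sitting/standing carries more metabolic cost per unit of
    # lower-body movement than quiet lab sitting, so the nominal levels
    # that set the *metabolic* side are higher for the stationary states.
    return {"sit": 60.0, "stand": 120.0, "slow_walk": 300.0, "brisk_walk": 600.0, "run": 1500.0}


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort generator."""

    n_participants: int = 34
    mode: str = "laboratory"  # or 'free_living'
    seed: int = 0
    true_curve: TrueCurve = field(default_factory=TrueCurve)
    noise_sd_met: float = 0.3  # breath-level noise, MET units
    vo2_lag_tau: float = 30.0  # first-order VO2 response constant, s
    position_gains: dict[str, float] = field(default_factory=_default_gains)
    wrist_decoupling_sd: float = 40.0  # mg of EE-independent wrist movement
    activity_mix: dict[str, float] = field(default_factory=_default_mix)
    lab_intensity_mg: dict[str, float] = field(default_factory=_default_lab_intensity)
    free_intensity_mg: dict[str, float] = field(default_factory=_default_free_intensity)
    free_living_intensity_scale: float = 0.6
    minute_jitter_sd: float = 0.1  # lognormal sigma on block intensity
    participant_scale_sd: float = 0.1  # lognormal sigma between participants
    sample_rate: float = 100.0
    session_minutes: int = 60  # free-living session length
    breath_rate_range: tuple[float, float] = (15.0, 30.0)
    body_mass_mean: float = 78.0
    body_mass_sd: float = 12.0

    def __post_init__(self) -> None:
        if self.mode not in ("laboratory", "free_living"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.noise_sd_met < 0 or self.vo2_lag_tau < 0:
            raise ValueError("noise_sd_met and vo2_lag_tau must be non-negative")
        if any(g <= 0 for g in self.position_gains.values()):
            raise ValueError("position gains must be positive")
        if self.wrist_decoupling_sd < 0:
            raise ValueError("wrist_decoupling_sd must be non-negative")
        total = sum(self.activity_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"activity_mix proportions must sum to 1, got {total}")
        unknown = set(self.activity_mix) - set(ACTIVITIES)
        if unknown:
            raise ValueError(f"unknown activities in mix: {sorted(unknown)}")

    # -- manifest round-trip ---------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["breath_rate_range"] = list(self.breath_rate_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["true_curve"] = TrueCurve(**d["true_curve"])
        d["breath_rate_range"] = tuple(d["breath_rate_range"])
        return cls(**d)


@dataclass
class ParticipantData:
    """Everything the generator knows about one synthetic participant."""

    participant_id: str
    body_mass: float
    recordings: dict[str, TriaxialRecording]
    breaths: BreathSeries
    bouts: list[ActivityBout]
    truth: METSeries  # noiseless, lag-free ground-truth minute METs
    schedule: pd.DataFrame  # block-level: activity, start, duration, movement and MET truth


def _rng(config: SimulationConfig, index: int, stream: int) -> np.random.Generator:
    # independent, order-insensitive streams per purpose
    return np.random.default_rng([config.seed, index, stream])


def _build_schedule(config: SimulationConfig, index: int) -> pd.DataFrame:
    rng = _rng(config, index, 0)
    pscale = float(np.exp(rng.normal(0.0, config.participant_scale_sd)))
    rows = []
    if config.mode == "laboratory":
        for k, act in enumerate(ACTIVITIES):
            x_nom = config.lab_intensity_mg[act] * pscale * float(
                np.exp(rng.normal(0.0, config.minute_jitter_sd))
            )
            rows.append(
                {
                    "activity": act,
                    "start": 240.0 * k,
                    "duration": 240.0,
                    "true_intensity": x_nom,
                    "movement_intensity": x_nom,
                    "true_met": config.true_curve.met(x_nom),
                }
            )
    else:
        acts = list(config.activity_mix)
        probs = np.array([config.activity_mix[a] for a in acts])
        choices = rng.choice(len(acts), size=config.session_minutes, p=probs)
        jitter = np.exp(rng.normal(0.0, config.minute_jitter_sd, config.session_minutes))
        for m, (c, j) in enumerate(zip(choices, jitter)):
            act = acts[c]
            x_nom = config.free_intensity_mg[act] * pscale * float(j)
            rows.append(
                {
                    "activity": act,
                    "start": MINUTE * m,
                    "duration": MINUTE,
                    "true_intensity": x_nom,
                    "movement_intensity": x_nom * config.free_living_intensity_scale,
                    "true_met": config.true_curve.met(x_nom),
                }
            )
    return pd.DataFrame(rows)


def _met_trace(schedule: pd.DataFrame, total_s: int) -> np.ndarray:
    """Per-second ground-truth MET trace (step function over blocks)."""
    trace = np.empty(total_s)
    for row in schedule.itertuples():
        i0 = int(row.start)
        trace[i0 : i0 + int(row.duration)] = row.true_met
    return trace


def _simulate_position(
    config: SimulationConfig,
    schedule: pd.DataFrame,
    position: str,
    rng: np.random.Generator,
    participant_id: str,
) -> TriaxialRecording:
    fs = config.sample_rate
    total_s = float(schedule["start"].iloc[-1] + schedule["duration"].iloc[-1])
    n = int(round(total_s * fs))
    gain = config.position_gains[position]
    sos_spec = FilterSpec()
    sos = sos_spec.sos(fs)

    # Unscaled movement: white noise shaped per axis, plus a gait harmonic
    # (fundamental + first overtone) during locomotor blocks.
    move = rng.standard_normal((3, n)) * _AXIS_WEIGHTS[:, None]
    t = np.arange(n) / fs
    for row in schedule.itertuples():
        act = row.activity
        if act in _LOCOMOTOR:
            i0 = int(round(row.start * fs))
            i1 = i0 + int(round(row.duration * fs))
            f = _LOCOMOTOR[act]
            phase = rng.uniform(0, 2 * np.pi)
            harmonic = 1.5 * np.sin(2 * np.pi * f * t[i0:i1] + phase)
            harmonic += 0.6 * np.sin(2 * np.pi * 2 * f * t[i0:i1] + 2 * phase)
            move[0, i0:i1] += harmonic
            move[2, i0:i1] += 0.7 * harmonic

    # Wrist fidgeting during stationary blocks: movement independent of EE.
    decouple = np.zeros((3, n))
    decouple_targets = np.zeros(len(schedule))
    if position == "wrist" and config.wrist_decoupling_sd > 0:
        for k, row in enumerate(schedule.itertuples()):
            if row.activity in _STATIONARY:
                i0 = int(round(row.start * fs))
                i1 = i0 + int(round(row.duration * fs))
                decouple[:, i0:i1] = rng.standard_normal((3, i1 - i0)) * _AXIS_WEIGHTS[:, None]
                decouple_targets[k] = abs(rng.normal(0.0, config.wrist_decoupling_sd))

    # Normalize block-by-block so that the band-pass vector-magnitude mean
    # of each movement component matches its target intensity.
    from scipy.signal import sosfiltfilt

    def _block_scaled(signal: np.ndarray, targets: np.ndarray) -> np.ndarray:
        filtered = sosfiltfilt(sos, signal, axis=1)
        vm = 1000.0 * np.sqrt((filtered**2).sum(axis=0))  # mg
        out = np.zeros_like(signal)
        for k, row in enumerate(schedule.itertuples()):
            target = targets[k]
            if target <= 0:
                continue
            i0 = int(round(row.start * fs))
            i1 = i0 + int(round(row.duration * fs))
            mean_vm = vm[i0:i1].mean()
            if mean_vm > 0:
                out[:, i0:i1] = signal[:, i0:i1] * (target / mean_vm)
        return out

    movement = _block_scaled(move, gain * schedule["movement_intensity"].to_numpy())
    if decouple_targets.any():
        movement += _block_scaled(decouple, decouple_targets)

    # Gravity: unit vector with slow orientation sway, far below the
    # high-pass corner so the filter removes it entirely.
    theta = 0.15 * np.sin(2 * np.pi * 0.02 * t + rng.uniform(0, 2 * np.pi))
    gravity = np.vstack([np.sin(theta), np.zeros(n), np.cos(theta)])

    acc = np.clip(gravity + movement, -16.0, 16.0)
    return TriaxialRecording(
        participant_id=participant_id,
        position=position,
        sample_rate=fs,
        x=acc[0],
        y=acc[1],
        z=acc[2],
    )


def _simulate_breaths(
    config: SimulationConfig,
    schedule: pd.DataFrame,
    body_mass: float,
    rng: np.random.Generator,
    participant_id: str,
) -> BreathSeries:
    total_s = int(schedule["start"].iloc[-1] + schedule["duration"].iloc[-1])
    met = _met_trace(schedule, total_s)

    if config.vo2_lag_tau > 0:
        alpha = 1.0 - np.exp(-1.0 / config.vo2_lag_tau)
        lagged = np.empty_like(met)
        lagged[0] = met[0]
        for i in range(1, met.size):
            lagged[i] = alpha * met[i] + (1 - alpha) * lagged[i - 1]
    else:
        lagged = met

    rate = rng.uniform(*config.breath_rate_range)  # breaths per minute
    mean_interval = 60.0 / rate
    n_max = int(total_s / mean_interval * 2) + 20
    intervals = np.maximum(rng.exponential(mean_interval, n_max), 0.2)
    times = np.cumsum(intervals)
    times = times[times < total_s]

    resting = body_mass * 3.5  # mL/min at 1 MET
    vo2 = resting * lagged[np.floor(times).astype(int)]
    if config.noise_sd_met > 0:
        vo2 = vo2 + rng.normal(0.0, config.noise_sd_met * resting, times.size)
    vo2 = np.maximum(vo2, 0.05 * resting)
    return BreathSeries(
        participant_id=participant_id, breath_time=times, vo2=vo2, body_mass=body_mass
    )


def simulate_participant(
    config: SimulationConfig,
    participant_index: int,
    positions: tuple[str, ...] | list[str] | None = None,
) -> ParticipantData:
    """Generate one synthetic participant.

    ``positions`` restricts which sensor streams are generated (default:
    the four study positions plus the nine segment sensors); the
    schedule, truth and breath series are unaffected by the choice.
    """
    if positions is None:
        positions = STUDY_POSITIONS + SEGMENTS
    unknown = set(positions) - set(POSITIONS)
    if unknown:
        raise ValueError(f"unknown positions: {sorted(unknown)}")

    pid = f"P{participant_index:03d}"
    schedule = _build_schedule(config, participant_index)

    rng_traits = _rng(config, participant_index, 1)
    body_mass = float(
        np.clip(rng_traits.normal(config.body_mass_mean, config.body_mass_sd), 45.0, 140.0)
    )
    breaths = _simulate_breaths(
        config, schedule, body_mass, _rng(config, participant_index, 2), pid
    )

    recordings = {}
    for pos in positions:
        stream = 10 + POSITIONS.index(pos)
        recordings[pos] = _simulate_position(
            config, schedule, pos, _rng(config, participant_index, stream), pid
        )

    total_s = int(schedule["start"].iloc[-1] + schedule["duration"].iloc[-1])
    met = _met_trace(schedule, total_s)
    n_minutes = total_s // int(MINUTE)
    truth = METSeries(
        participant_id=pid,
        minute_start=MINUTE * np.arange(n_minutes),
        mets=met[: n_minutes * 60].reshape(n_minutes, 60).mean(axis=1),
    )

    bouts = []
    if config.mode == "laboratory":
        bouts = [
            ActivityBout(activity=row.activity, start=row.start, end=row.start + row.duration)
            for row in schedule.itertuples()
        ]

    return ParticipantData(
        participant_id=pid,
        body_mass=body_mass,
        recordings=recordings,
        breaths=breaths,
        bouts=bouts,
        truth=truth,
        schedule=schedule,
    )


def simulate_cohort(
    config: SimulationConfig,
    outdir: str | Path,
    positions: tuple[str, ...] | list[str] | None = None,
    force: bool = False,
) -> list[Path]:
    """Generate a cohort and write it as the package's CSV/JSON formats.

    Layout: ``manifest.json`` at the root (config round-trips through
    it), one folder per participant with ``acc_<position>.csv``,
    ``breaths.csv``, ``truth_mets.csv``, ``metadata.json`` and, in
    laboratory mode, ``bouts.csv``.
    """
    from . import io as accio

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(
        json.dumps({"format": "accmet-cohort-v1", "config": config.to_dict()}, indent=2)
    )

    paths = []
    group = "laboratory" if config.mode == "laboratory" else "industrial_production"
    for i in range(1, config.n_participants + 1):
        part = simulate_participant(config, i, positions)
        pdir = outdir / part.participant_id
        pdir.mkdir(exist_ok=True)
        (pdir / "metadata.json").write_text(
            json.dumps(
                {
                    "participant_id": part.participant_id,
                    "body_mass": part.body_mass,
                    "group": group,
                },
                indent=2,
            )
        )
        for pos, rec in part.recordings.items():
            accio.write_triaxial_csv(pdir / f"acc_{pos}.csv", rec)
        accio.write_breath_csv(pdir / "breaths.csv", part.breaths)
        accio.write_met_csv(pdir / "truth_mets.csv", part.truth)
        if part.bouts:
            pd.DataFrame(
                [{"activity": b.activity, "start_s": b.start, "end_s": b.end} for b in part.bouts]
            ).to_csv(pdir / "bouts.csv", index=False)
        paths.append(pdir)
    return paths


def load_manifest(path: str | Path) -> SimulationConfig:
    """Read a cohort manifest back into its SimulationConfig."""
    d = json.loads(Path(path).read_text())
    return SimulationConfig.from_dict(d["config"])
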