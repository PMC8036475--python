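"""File formats: delimited-text readers and writers, metadata, reports.

All tabular interchange is headered CSV; models and reports are JSON.
Time columns are seconds on the session clock (``time_s``,
``epoch_start_s``, ``minute_start_s``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CutPointSet
from .energy_expenditure import ActivityBout, BreathSeries, METSeries
from .signal_processing import IntensitySeries, TriaxialRecording
from .workload import SegmentWeightTable

__all__ = [
    "ParticipantMetadata",
    "read_triaxial_csv",
    "write_triaxial_csv",
    "read_intensity_csv",
    "write_intensity_csv",
    "read_breath_csv",
    "write_breath_csv",
    "read_met_csv",
    "write_met_csv",
    "read_bouts_csv",
    "read_metadata",
    "read_weights_json",
    "write_weights_json",
    "cutpoints_table",
    "write_cutpoints_csv",
]

GROUPS = ("laboratory", "logistics_warehouse", "industrial_production")


@dataclass
class ParticipantMetadata:
    participant_id: str
    body_mass: float
    group: str = "laboratory"
    age: float | None = None
    sex: str | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def _read_csv(path: str | Path, required: tuple[str, ...], delimiter: str = ",") -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, delimiter=delimiter)
    except Exception as err:  # noqa: BLE001 - re-raise with the file named
        raise ValueError(f"{path}: malformed CSV ({err})") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df[list(required)].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: missing value at line {line}")
    return df


def read_triaxial_csv(
    path: str | Path,
    participant_id: str = "",
    position: str = "hip",
    delimiter: str = ",",
) -> TriaxialRecording:
    """Read raw acceleration from CSV with columns time_s, x_g, y_g, z_g.

    The sample rate is inferred from the median time step; timestamps
    must be uniform (no resampling is performed, as the filter corner
    frequencies are absolute).
    """
    df = _read_csv(path, ("time_s", "x_g", "y_g", "z_g"), delimiter)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or np.any(np.abs(steps - dt) > 0.01 * dt):
        raise ValueError(f"{path}: time steps are not uniform")
    return TriaxialRecording(
        participant_id=participant_id,
        position=position,
        sample_rate=1.0 / dt,
        start_time=float(t[0]),
        x=df["x_g"].to_numpy(dtype=float),
        y=df["y_g"].to_numpy(dtype=float),
        z=df["z_g"].to_numpy(dtype=float),
    )


def write_triaxial_csv(path: str | Path, rec: TriaxialRecording) -> None:
    t = rec.start_time + np.arange(rec.n_samples) / rec.sample_rate
    pd.DataFrame({"time_s": t, "x_g": rec.x, "y_g": rec.y, "z_g": rec.z}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_intensity_csv(
    path: str | Path, participant_id: str = "", position: str = "hip"
) -> IntensitySeries:
    df = _read_csv(path, ("epoch_start_s", "epoch_length_s", "intensity_mg"))
    return IntensitySeries(
        participant_id=participant_id,
        position=position,
        epoch_start=df["epoch_start_s"].to_numpy(dtype=float),
        epoch_length=float(df["epoch_length_s"].iloc[0]),
        intensity=df["intensity_mg"].to_numpy(dtype=float),
    )


def write_intensity_csv(path: str | Path, series: IntensitySeries) -> None:
    pd.DataFrame(
        {
            "epoch_start_s": series.epoch_start,
            "epoch_length_s": series.epoch_length,
            "intensity_mg": series.intensity,
        }
    ).to_csv(path, index=False)


def read_breath_csv(path: str | Path, body_mass: float, participant_id: str = "") -> BreathSeries:
    df = _read_csv(path, ("time_s", "vo2_ml_min"))
    return BreathSeries(
        participant_id=participant_id,
        breath_time=df["time_s"].to_numpy(dtype=float),
        vo2=df["vo2_ml_min"].to_numpy(dtype=float),
        body_mass=body_mass,
    )


def write_breath_csv(path: str | Path, breaths: BreathSeries) -> None:
    pd.DataFrame({"time_s": breaths.breath_time, "vo2_ml_min": breaths.vo2}).to_csv(
        path, index=False, float_format="%.4f"
    )


def read_met_csv(path: str | Path, participant_id: str = "") -> METSeries:
    df = _read_csv(path, ("minute_start_s", "mets"))
    return METSeries(
        participant_id=participant_id,
        minute_start=df["minute_start_s"].to_numpy(dtype=float),
        mets=df["mets"].to_numpy(dtype=float),
    )


def write_met_csv(path: str | Path, mets: METSeries) -> None:
    pd.DataFrame({"minute_start_s": mets.minute_start, "mets": mets.mets}).to_csv(
        path, index=False
    )


def read_bouts_csv(path: str | Path) -> list[ActivityBout]:
    df = _read_csv(path, ("activity", "start_s", "end_s"))
    return [
        ActivityBout(activity=r.activity, start=float(r.start_s), end=float(r.end_s))
        for r in df.itertuples()
    ]


def read_metadata(path: str | Path) -> ParticipantMetadata:
    d = json.loads(Path(path).read_text())
    return ParticipantMetadata(**d)


def read_weights_json(path: str | Path) -> SegmentWeightTable:
    return SegmentWeightTable(fractions=json.loads(Path(path).read_text()))


def write_weights_json(path: str | Path, table: SegmentWeightTable) -> None:
    Path(path).write_text(json.dumps(dict(table.fractions), indent=2))


def cutpoints_table(cutpoint_sets: list[CutPointSet]) -> pd.DataFrame:
    """Wide cut-point table: one row per source x threshold, one column
    per position (the layout in which cut-points are usually reported)."""
    long = pd.concat([c.to_frame() for c in cutpoint_sets], ignore_index=True)
    wide = long.pivot_table(
        index=["source", "threshold_met"],
        columns="position",
        values="cutpoint_mg",
        dropna=False,
    )
    wide.columns.name = None
    return wide.reset_index()


def write_cutpoints_csv(path: str | Path, cutpoint_sets: list[CutPointSet]) -> None:
    cutpoints_table(cutpoint_sets).to_csv(path, index=False, float_format="%.1f")
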