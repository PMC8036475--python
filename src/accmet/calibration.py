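"""Intensity-to-MET calibration: spline fits, prediction, and cut-points.

A calibration model maps epoch movement intensity (mg) to energy
expenditure (METs) with a penalized cubic smoothing spline (normalized
smoothing parameter, default 0.2; see :mod:`accmet.smoothing` for the
exact normalization — derived cut-points are sensitive to it).
Cut-points are the intensities at which the fitted curve crosses chosen
MET thresholds (1.5, 3, 6 and 9 METs by default), found by bracketing on
a 1 mg grid and Brent root refinement; a threshold the fitted curve never
reaches is reported as undefined rather than extrapolated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PPoly
from scipy.optimize import brentq

from .energy_expenditure import ActivityBout, METSeries, steady_state_met
from .signal_processing import IntensitySeries
from .smoothing import normalized_lambda, smoothing_spline, weighted_line

__all__ = [
    "DEFAULT_SMOOTHING",
    "DEFAULT_THRESHOLDS",
    "CalibrationModel",
    "CutPointSet",
    "fit_smoothing_spline",
    "predict_ee",
    "derive_cutpoints",
    "laboratory_calibration_pairs",
]

DEFAULT_SMOOTHING = 0.2
DEFAULT_THRESHOLDS = (1.5, 3.0, 6.0, 9.0)

#: Cut-point bracketing grid step (mg) and root tolerance (mg).
_GRID_STEP_MG = 1.0
_ROOT_XTOL_MG = 1e-9


@dataclass
class CalibrationModel:
    """Fitted intensity (mg) -> MET calibration curve.

    The curve is stored as breakpoints plus piecewise cubic coefficients
    (one column per piece, highest degree first, in local coordinates
    ``x - breakpoints[i]``) so that predictions are reproducible
    bit-identically after JSON round-trips, independent of the fitting
    library.
    """

    position: str
    source: str  # 'laboratory' or 'free_living'
    smoothing_param: float
    x_range: tuple[float, float]
    r_squared: float
    breakpoints: np.ndarray
    coefficients: np.ndarray
    n_obs: int = 0

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not 0 <= self.smoothing_param <= 1:
            raise ValueError("smoothing_param must be in [0, 1]")
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared must be in [0, 1]")

    def _ppoly(self) -> PPoly:
        return PPoly(self.coefficients, self.breakpoints, extrapolate=True)

    def _evaluate(self, x: np.ndarray) -> np.ndarray:
        """Raw spline evaluation with range clamping, no MET floor."""
        lo, hi = self.x_range
        return self._ppoly()(np.clip(x, lo, hi))

    def predict(self, intensity_mg: np.ndarray | float) -> np.ndarray:
        """Predict METs at the given intensities.

        Intensities outside the calibrated range are clamped to the range
        endpoints, and negative spline values are floored at 0 METs; both
        conditions emit a warning.
        """
        x = np.atleast_1d(np.asarray(intensity_mg, dtype=float))
        lo, hi = self.x_range
        n_clamped = int(np.sum((x < lo) | (x > hi)))
        if n_clamped:
            warnings.warn(
                f"{n_clamped} intensities outside the calibrated range "
                f"[{lo:.1f}, {hi:.1f}] mg were clamped",
                stacklevel=2,
            )
        out = self._evaluate(x)
        if np.any(out < 0):
            warnings.warn("negative MET predictions floored at 0", stacklevel=2)
            out = np.maximum(out, 0.0)
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "position": self.position,
            "source": self.source,
            "smoothing_param": self.smoothing_param,
            "x_range": list(self.x_range),
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
            "breakpoints": self.breakpoints.tolist(),
            "coefficients": self.coefficients.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            position=d["position"],
            source=d["source"],
            smoothing_param=d["smoothing_param"],
            x_range=tuple(d["x_range"]),
            r_squared=d["r_squared"],
            n_obs=d.get("n_obs", 0),
            breakpoints=np.array(d["breakpoints"], dtype=float),
            coefficients=np.array(d["coefficients"], dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CutPointSet:
    """Intensity cut-points (mg) for a set of MET thresholds.

    ``cutpoints[T]`` is None when the fitted curve never reaches T inside
    the calibrated intensity range; ``status[T]`` says on which side
    ('below_calibrated_range' when the curve sits entirely above T,
    'above_calibrated_range' when it never climbs to T).
    """

    position: str
    source: str
    thresholds: tuple[float, ...]
    cutpoints: dict[float, float | None]
    status: dict[float, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "threshold_met": t,
                "cutpoint_mg": self.cutpoints[t],
                "status": self.status.get(t, "ok"),
            }
            for t in self.thresholds
        ]
        df = pd.DataFrame(rows)
        df.insert(0, "source", self.source)
        df.insert(0, "position", self.position)
        return df


def _group_duplicates(x: np.ndarray, y: np.ndarray):
    """Sort sites and average replicate responses, keeping counts as weights."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    xu, start = np.unique(xs, return_index=True)
    counts = np.diff(np.append(start, xs.size))
    sums = np.add.reduceat(ys, start)
    return xu, sums / counts, counts.astype(float)


def fit_smoothing_spline(
    x: np.ndarray,
    y: np.ndarray,
    smoothing_param: float = DEFAULT_SMOOTHING,
    *,
    position: str = "",
    source: str = "laboratory",
) -> CalibrationModel:
    """Fit the normalized-parameter smoothing spline calibration.

    Replicate x sites are merged to their mean response with weight equal
    to the replicate count, which leaves the penalized objective over the
    original observations unchanged.  ``smoothing_param = 0`` yields the
    weighted least-squares line; ``1`` the natural interpolating spline.
    R^2 is 1 - SSE/SST over the original training observations; because
    the straight line is penalty-free, the fitted spline never does worse
    than the least-squares line and R^2 lands in [0, 1].
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in calibration data")
    if not 0 <= smoothing_param <= 1:
        raise ValueError("smoothing_param must be in [0, 1]")
    xu, yu, w = _group_duplicates(x, y)
    if xu.size < 4:
        raise ValueError(f"need at least 4 distinct x values, got {xu.size}")

    if smoothing_param == 0:
        pp = weighted_line(xu, yu, w)
    else:
        lam = normalized_lambda(smoothing_param, xu)
        pp = smoothing_spline(xu, yu, lam, w)

    fitted = pp(x)
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        r2 = 1.0 if sse < 1e-12 else 0.0
    else:
        r2 = 1.0 - sse / sst
    r2 = float(min(1.0, max(0.0, r2)))

    return CalibrationModel(
        position=position,
        source=source,
        smoothing_param=smoothing_param,
        x_range=(float(xu[0]), float(xu[-1])),
        r_squared=r2,
        breakpoints=pp.x,
        coefficients=pp.c,
        n_obs=int(x.size),
    )


def predict_ee(model: CalibrationModel, intensity: IntensitySeries) -> pd.Series:
    """Estimated METs per epoch of an intensity series.

    Returns a Series indexed by epoch start time (seconds); values may be
    0 where the floored spline predicts no metabolic cost above rest.
    """
    est = model.predict(intensity.intensity)
    return pd.Series(est, index=intensity.epoch_start, name="estimated_met")


def derive_cutpoints(
    model: CalibrationModel, thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
) -> CutPointSet:
    """Invert the calibration curve at the given MET thresholds.

    For each threshold T the cut-point is the *smallest* intensity in the
    calibrated range where the fitted curve equals T (bracketing on a
    1 mg grid, then Brent refinement).  Thresholds the curve never
    reaches are reported as undefined with a status, mirroring the fact
    that a calibration with no data at an intensity cannot define a
    cut-point there.
    """
    lo, hi = model.x_range
    grid = np.append(np.arange(lo, hi, _GRID_STEP_MG), hi)
    vals = model._evaluate(grid)
    pp = model._ppoly()

    cutpoints: dict[float, float | None] = {}
    status: dict[float, str] = {}
    for t in thresholds:
        diff = vals - t
        if np.all(diff > 0):
            cutpoints[t] = None
            status[t] = "below_calibrated_range"
            continue
        if np.all(diff < 0):
            cutpoints[t] = None
            status[t] = "above_calibrated_range"
            continue
        cross = np.nonzero(diff[:-1] * diff[1:] <= 0)[0]
        if diff[0] == 0:
            root = float(grid[0])
        else:
            i = int(cross[0])
            if diff[i] == 0:
                root = float(grid[i])
            elif diff[i + 1] == 0 and (i + 1 == grid.size - 1 or diff[i + 2] * diff[i + 1] >= 0):
                root = float(grid[i + 1])
            else:
                root = float(
                    brentq(lambda v: pp(v) - t, grid[i], grid[i + 1], xtol=_ROOT_XTOL_MG)
                )
        cutpoints[t] = root
        status[t] = "ok"
    return CutPointSet(
        position=model.position,
        source=model.source,
        thresholds=tuple(thresholds),
        cutpoints=cutpoints,
        status=status,
    )


def laboratory_calibration_pairs(
    intensity: IntensitySeries,
    mets: METSeries,
    bouts: list[ActivityBout],
    window: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One (intensity, MET) calibration pair per laboratory activity bout.

    The MET value is the steady-state mean over the final ``window``
    seconds of the bout; the intensity value is the mean of the epochs
    fully inside that same window, so both sides describe the same
    steady-state interval.
    """
    xs, ys = [], []
    for bout in bouts:
        lo = bout.end - window
        in_window = (intensity.epoch_start >= lo - 1e-9) & (
            intensity.epoch_start + intensity.epoch_length <= bout.end + 1e-9
        )
        if not np.any(in_window):
            raise ValueError(
                f"no intensity epochs inside the final {window:g} s of bout "
                f"{bout.activity!r}"
            )
        xs.append(float(intensity.intensity[in_window].mean()))
        ys.append(steady_state_met(mets, bout, window=window))
    return np.array(xs), np.array(ys)
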