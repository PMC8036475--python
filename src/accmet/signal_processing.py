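"""Raw triaxial acceleration to epoch-level movement intensity.

The processing chain is the frequency-extended band-pass method used in
physical-activity research: each acceleration axis is filtered with a
zero-phase Butterworth band-pass (0.69–10 Hz by default), the three
filtered axes are combined to a vector magnitude, and the magnitude is
averaged over fixed epochs.  The high-pass component removes the gravity
component and slow orientation drift; the low-pass component removes
sensor noise above the frequency range of human movement.

Intensities are reported in mg (milli-g, 1 mg = 0.001 g); internal
computation stays in g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "POSITIONS",
    "TriaxialRecording",
    "FilterSpec",
    "IntensitySeries",
    "band_pass_filter",
    "vector_magnitude",
    "aggregate_epochs",
    "process_recording",
    "filter_frequency_response",
]

#: Recognised sensor positions: the four study positions plus the nine
#: body-segment reference sensors.
POSITIONS = (
    "shoe",
    "hip",
    "thigh",
    "wrist",
    "shank_L",
    "shank_R",
    "thigh_L",
    "thigh_R",
    "upper_arm_L",
    "upper_arm_R",
    "forearm_L",
    "forearm_R",
    "trunk",
    "full_body",  # derived channel: segment-weighted workload sum
)

#: Acceleration range of the device in g; samples outside are rejected.
DEVICE_RANGE_G = 16.0

#: Length of the edge region (seconds) flagged as filter transient.
TRANSIENT_SECONDS = 2.0


class FilterError(ValueError):
    """Invalid filter design or a recording too short to filter."""


@dataclass
class TriaxialRecording:
    """One participant x position stream of raw triaxial acceleration.

    Axes are in g, sampled uniformly at ``sample_rate`` Hz; the time of
    sample ``i`` is ``start_time + i / sample_rate`` seconds.
    """

    participant_id: str
    position: str
    sample_rate: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal length")
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}")
        for name, axis in (("x", self.x), ("y", self.y), ("z", self.z)):
            if np.any(np.abs(axis) > DEVICE_RANGE_G):
                raise ValueError(
                    f"axis {name} exceeds the +/-{DEVICE_RANGE_G:g} g device range"
                )

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: high-pass and low-pass corner frequencies in Hz."""

    high_pass_hz: float = 0.69
    low_pass_hz: float = 10.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.high_pass_hz < self.low_pass_hz:
            raise FilterError("need 0 < high_pass_hz < low_pass_hz")
        if self.order < 1:
            raise FilterError("order must be a positive integer")

    def sos(self, sample_rate: float) -> np.ndarray:
        """Second-order-section Butterworth design for a given sample rate."""
        nyquist = sample_rate / 2.0
        if self.low_pass_hz >= nyquist:
            raise FilterError(
                f"low-pass corner {self.low_pass_hz} Hz is at or above the "
                f"Nyquist frequency {nyquist} Hz"
            )
        return sps.butter(
            self.order,
            [self.high_pass_hz, self.low_pass_hz],
            btype="bandpass",
            fs=sample_rate,
            output="sos",
        )

    def pad_samples(self, sample_rate: float) -> int:
        # Reflection padding must outlast the slow high-pass transient
        # (~1/high_pass_hz seconds), not just the filter order.
        return int(np.ceil(3.0 * sample_rate / self.high_pass_hz))


@dataclass
class IntensitySeries:
    """Epoch-aggregated movement intensity in mg.

    Epochs are half-open ``[epoch_start, epoch_start + epoch_length)``
    intervals; ``epoch_start`` is in seconds on the recording clock.
    Epochs need not be gap-free (transient or masked epochs may have been
    dropped) but never overlap.
    """

    participant_id: str
    position: str
    epoch_start: np.ndarray
    epoch_length: float
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.epoch_start = np.asarray(self.epoch_start, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if len(self.epoch_start) != len(self.intensity):
            raise ValueError("epoch_start and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if len(self.epoch_start) > 1:
            gaps = np.diff(self.epoch_start)
            if np.any(gaps < self.epoch_length - 1e-9):
                raise ValueError("epochs overlap")

    def __len__(self) -> int:
        return len(self.intensity)


def band_pass_filter(rec: TriaxialRecording, spec: FilterSpec | None = None) -> TriaxialRecording:
    """Apply the band-pass filter to each axis of a recording.

    Each axis is filtered independently with the same forward-backward
    (zero-phase) Butterworth band-pass, after reflect-padding both ends to
    absorb the high-pass warm-up transient.  Output length equals input
    length; the DC (gravity) component is removed.

    Raises
    ------
    FilterError
        If a corner frequency is at or above Nyquist, or the recording is
        shorter than the filter warm-up length.
    """
    spec = spec or FilterSpec()
    sos = spec.sos(rec.sample_rate)
    pad = spec.pad_samples(rec.sample_rate)
    if rec.n_samples <= pad:
        raise FilterError(
            f"recording of {rec.n_samples} samples is shorter than the "
            f"filter warm-up length of {pad} samples"
        )

    def _filter(axis: np.ndarray) -> np.ndarray:
        padded = np.pad(axis, pad, mode="reflect")
        if spec.zero_phase:
            out = sps.sosfiltfilt(sos, padded, padlen=0)
        else:
            out = sps.sosfilt(sos, padded)
        return out[pad:-pad]

    return replace(rec, x=_filter(rec.x), y=_filter(rec.y), z=_filter(rec.z))


def vector_magnitude(rec: TriaxialRecording) -> np.ndarray:
    """Per-sample Euclidean norm of the three (filtered) axes, in mg."""
    return 1000.0 * np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)


def aggregate_epochs(
    samples: np.ndarray,
    sample_rate: float,
    epoch_length: float,
    *,
    participant_id: str = "",
    position: str = "hip",
    start_time: float = 0.0,
    transient_seconds: float = 0.0,
) -> IntensitySeries:
    """Average a sample-rate intensity sequence into fixed epochs.

    Each epoch value is the arithmetic mean of the samples falling in
    ``[start, start + epoch_length)``; a trailing partial epoch is
    dropped.  When ``transient_seconds`` > 0, samples within that distance
    of either end of the series are considered filter transients: an epoch
    consisting entirely of transient samples is dropped, while epochs that
    merely contain some transient samples keep their full mean.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty intensity sequence")
    per_epoch = int(round(epoch_length * sample_rate))
    if per_epoch < 1:
        raise ValueError("epoch_length * sample_rate must be >= 1")
    n_epochs = samples.size // per_epoch
    if n_epochs == 0:
        raise ValueError("input shorter than one epoch")
    trimmed = samples[: n_epochs * per_epoch].reshape(n_epochs, per_epoch)
    means = trimmed.mean(axis=1)
    starts = start_time + epoch_length * np.arange(n_epochs)

    if transient_seconds > 0:
        t_lo = transient_seconds
        t_hi = samples.size / sample_rate - transient_seconds
        rel = starts - start_time
        fully_transient = (rel + epoch_length <= t_lo) | (rel >= t_hi)
        means = means[~fully_transient]
        starts = starts[~fully_transient]

    return IntensitySeries(
        participant_id=participant_id,
        position=position,
        epoch_start=starts,
        epoch_length=float(epoch_length),
        intensity=means,
    )


def process_recording(
    rec: TriaxialRecording,
    spec: FilterSpec | None = None,
    epoch_length: float = 60.0,
) -> IntensitySeries:
    """Full chain: band-pass filter, vector magnitude, epoch aggregation.

    The first/last 2 s are flagged as filter transients (see
    :func:`aggregate_epochs`).  Filtering each axis before taking the
    vector magnitude is deliberate: the reverse order is not equivalent,
    because the norm is a nonlinear operation that mixes the gravity
    component into all frequencies.
    """
    filtered = band_pass_filter(rec, spec)
    vm = vector_magnitude(filtered)
    return aggregate_epochs(
        vm,
        rec.sample_rate,
        epoch_length,
        participant_id=rec.participant_id,
        position=rec.position,
        start_time=rec.start_time,
        transient_seconds=TRANSIENT_SECONDS,
    )


def filter_frequency_response(
    spec: FilterSpec, sample_rate: float, freqs_hz: np.ndarray
) -> np.ndarray:
    """Magnitude gain of the designed filter at the given frequencies.

    For a zero-phase (forward-backward) application the effective gain is
    the squared magnitude of the single-pass transfer function.
    """
    sos = spec.sos(sample_rate)
    _, h = sps.sosfreqz(sos, worN=np.atleast_1d(freqs_hz), fs=sample_rate)
    gain = np.abs(h)
    return gain**2 if spec.zero_phase else gain
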