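"""Shared data containers for the CaV1.2 coupling analysis pipeline.

Conventions used throughout the package:

* images and movies are indexed ``(frame, row, col)``, 0-based, with pixel
  centers at integer coordinates;
* traces are uniformly sampled; ``time[i] = i / fs``;
* fluorescence calibrated to Ca2+ concentration is always in nM, currents
  in pA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "ChannelRecord",
    "MovieStack",
    "ActivityStat",
]


class ValidationError(ValueError):
    """Raised when an input fails a precondition (exit code 2 in the CLI)."""


@dataclass
class ChannelRecord:
    """A uniformly sampled current or fluorescence trace.

    Parameters
    ----------
    values : np.ndarray
        Sample values (pA for currents, nM for calibrated Ca2+ signals).
    fs : float
        Sampling rate in Hz.
    amplitude : float
        Elementary event amplitude (single-channel current or quantal
        Ca2+ sparklet amplitude) in the same units as ``values``.
    units : str
        Unit label, e.g. ``"pA"`` or ``"nM"``.
    """

    values: np.ndarray
    fs: float
    amplitude: float | None = None
    units: str = "pA"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("ChannelRecord values must be 1-D")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class MovieStack:
    """An image time series: ``frames`` is (n_frames, n_rows, n_cols) float.

    ``frame_rate`` is in Hz, ``pixel_size`` in nm.  ``units`` records the
    calibration state of the pixel values ("au" for raw camera units,
    "nM" once converted to Ca2+ concentration, "" for dimensionless F/F0).
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float
    units: str = "au"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValidationError("MovieStack frames must be (t, rows, cols)")
        if not np.isfinite(self.frame_rate) or self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ActivityStat:
    """Time-averaged activity of a record: nPo for patches, nPs for sparklet
    sites.  ``value`` is the mean occupancy level (number of channels times
    open probability for exchangeable channels)."""

    value: float
    n_levels_observed: int
    total_time: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("activity cannot be negative")
        if self.n_levels_observed > 0 and self.value > self.n_levels_observed:
            raise ValidationError(
                "mean occupancy cannot exceed the maximum observed level"
            )
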