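"""File formats: delimited-text traces, TIFF movie stacks with sidecar
metadata, integer level sequences, and flat result tables.

Traces are 2-column delimited text (``time_s,value``) with a one-line
header; floats are serialized with 9 significant digits.  Movies are
multi-page 32-bit-float TIFF with a YAML sidecar carrying ``frame_rate_hz``
and ``pixel_size_nm`` (and the unit label).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ChannelRecord, MovieStack, ValidationError

__all__ = [
    "read_trace",
    "write_trace",
    "read_record",
    "read_stack",
    "write_stack",
    "read_levels",
    "write_levels",
    "write_table",
    "FormatError",
]


class FormatError(ValidationError):
    """Malformed input file."""


TRACE_HEADER = ("time_s", "value")


def write_trace(path: str | Path, t: np.ndarray, values: np.ndarray) -> Path:
    """Write a (time_s, value) trace with 9 significant digits."""
    path = Path(path)
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.shape != values.shape:
        raise ValidationError("time and value arrays must match")
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(TRACE_HEADER) + "\n")
        for ti, vi in zip(t, values):
            fh.write(f"{ti:.9g},{vi:.9g}\n")
    return path


def read_trace(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 2-column trace; malformed rows are reported with line numbers."""
    path = Path(path)
    with open(path, "r", newline=None) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = [c.strip() for c in lines[0].split(",")]
    if tuple(header[:2]) != TRACE_HEADER:
        raise FormatError(
            f"{path}: missing header; expected '{','.join(TRACE_HEADER)}', "
            f"got '{lines[0]}'"
        )
    t: list[float] = []
    v: list[float] = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) < 2:
            raise FormatError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
        try:
            t.append(float(parts[0]))
            v.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from exc
    return np.asarray(t), np.asarray(v)


def read_record(path: str | Path, amplitude: float | None = None) -> ChannelRecord:
    """Read a trace file into a ChannelRecord (fs from the time column)."""
    t, v = read_trace(path)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return ChannelRecord(values=v, fs=fs, amplitude=amplitude)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(path: str | Path, stack: MovieStack) -> Path:
    """Write a MovieStack as multi-page float32 TIFF + YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32))
    meta = {
        "frame_rate_hz": float(stack.frame_rate),
        "pixel_size_nm": float(stack.pixel_size),
        "units": stack.units,
        "n_frames": int(stack.n_frames),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def read_stack(
    path: str | Path,
    frame_rate: float | None = None,
    pixel_size: float | None = None,
) -> MovieStack:
    """Read a multi-page TIFF; metadata from the sidecar unless overridden.

    Integer TIFFs are promoted to float32 with exact values.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    frames = np.asarray(frames, dtype=np.float32)
    units = "au"
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        if "n_frames" in meta and int(meta["n_frames"]) != frames.shape[0]:
            raise FormatError(
                f"{sidecar}: sidecar says {meta['n_frames']} frames, "
                f"TIFF has {frames.shape[0]}"
            )
        frame_rate = frame_rate if frame_rate is not None else meta.get("frame_rate_hz")
        pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_nm")
        units = meta.get("units", units)
    missing = [
        k
        for k, val in (("frame_rate_hz", frame_rate), ("pixel_size_nm", pixel_size))
        if val is None
    ]
    if missing:
        raise FormatError(
            f"{path}: missing metadata {missing}; provide a sidecar "
            f"({sidecar.name}) or pass them explicitly"
        )
    return MovieStack(
        frames=frames, frame_rate=float(frame_rate), pixel_size=float(pixel_size),
        units=units,
    )


def write_levels(path: str | Path, levels: np.ndarray) -> Path:
    """Write an integer level sequence, one level per line."""
    path = Path(path)
    np.savetxt(path, np.asarray(levels, dtype=int), fmt="%d")
    return path


def read_levels(path: str | Path) -> np.ndarray:
    levels = np.loadtxt(path, dtype=int)
    return np.atleast_1d(levels)


def write_table(path: str | Path, df: pd.DataFrame) -> Path:
    """Write a flat result table as CSV (9 significant digits)."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.9g")
    return path
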