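"""Waveform extraction from M-mode and PW-Doppler images.

Wall tracing is threshold-based inside user-declared regions of interest:
for the near (anterior) wall the traced row is the deepest suprathreshold
pixel in the ROI, for the far (posterior) wall the shallowest — i.e. the
inner edge facing the lumen in both cases.  Diameter is inner edge to inner
edge.  The maximum Doppler envelope is the suprathreshold row farthest from
the baseline on the forward-flow side.

Gaps (columns with no suprathreshold pixel, declared artefact exclusions,
and automatically rejected outliers) are filled by a cubic smoothing spline.
The smoothing parameter ``p`` follows the classic penalized least-squares
convention: minimize ``p * sum (y - f)^2 + (1 - p) * integral f''^2``
(``p -> 1`` interpolates, ``p -> 0`` tends to the least-squares line), so it
maps onto :func:`scipy.interpolate.make_smoothing_spline` via
``lam = (1 - p) / p``.  The default ``p = 0.001``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .errors import AnatomyError, InsufficientDataError, TracingQualityError
from .image_io import UltrasoundRecording

__all__ = [
    "WallTrace",
    "RawWaveform",
    "trace_wall",
    "smooth_trace",
    "diameter_waveform",
    "trace_doppler_envelope",
]

DEFAULT_SMOOTHING = 0.001
MAX_MISSING_FRACTION = 0.6


@dataclass
class WallTrace:
    """Per-column wall row position; NaN marks missing columns."""

    rows: np.ndarray
    wall: str  # "near" or "far"
    roi: tuple[int, int]
    threshold: float
    exclusions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.wall not in ("near", "far"):
            raise ValueError(f"wall must be 'near' or 'far', got {self.wall!r}")
        self.exclusions = tuple((int(a), int(b)) for a, b in self.exclusions)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.rows)


@dataclass
class RawWaveform:
    """A calibrated per-column waveform: cm for diameter, m/s for velocity."""

    values: np.ndarray
    time_cal: float  # ms per column
    kind: str  # "diameter" or "velocity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("diameter", "velocity"):
            raise ValueError(f"kind must be 'diameter' or 'velocity', got {self.kind!r}")
        if not self.time_cal > 0:
            raise ValueError("time_cal must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform values must be finite after gap filling")
        if self.kind == "diameter" and np.any(self.values <= 0):
            raise ValueError("diameter values must be strictly positive")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.values.size) * self.time_cal


def _apply_exclusions(values: np.ndarray, exclusions: Sequence[tuple[int, int]]) -> None:
    for a, b in exclusions:
        values[max(0, a) : max(0, b)] = np.nan


def trace_wall(
    rec: UltrasoundRecording,
    wall: str,
    roi: tuple[int, int],
    threshold: float,
    exclusions: Sequence[tuple[int, int]] = (),
) -> WallTrace:
    """Trace one arterial wall's inner edge inside a row ROI.

    Raises :class:`TracingQualityError` when more than 60% of columns have
    no suprathreshold pixel (the threshold likely needs adjusting).
    """
    r0, r1 = int(roi[0]), int(roi[1])
    if not (0 <= r0 < r1 <= rec.pixels.shape[0]):
        raise ValueError(f"roi {roi} outside image with {rec.pixels.shape[0]} rows")
    sub = rec.pixels[r0:r1]
    mask = sub > threshold
    any_hit = mask.any(axis=0)
    rows = np.full(rec.n_columns, np.nan)
    if wall == "near":
        # deepest suprathreshold pixel = inner edge of the anterior wall
        idx = (r1 - 1) - np.argmax(mask[::-1], axis=0)
    elif wall == "far":
        idx = r0 + np.argmax(mask, axis=0)
    else:
        raise ValueError(f"wall must be 'near' or 'far', got {wall!r}")
    rows[any_hit] = idx[any_hit]
    _apply_exclusions(rows, exclusions)
    missing = np.mean(~np.isfinite(rows))
    if missing > MAX_MISSING_FRACTION:
        raise TracingQualityError(
            f"{wall} wall: {missing:.0%} of columns untraced; adjust threshold {threshold}"
        )
    return WallTrace(rows=rows, wall=wall, roi=(r0, r1), threshold=threshold, exclusions=tuple(exclusions))


def _drop_outliers(x: np.ndarray, y: np.ndarray, window: int = 31, n_mad: float = 3.0) -> np.ndarray:
    """Mask points more than ``n_mad`` MADs from a rolling median.

    Reproducible surrogate for the manual artefact cleaning step; returns a
    boolean keep-mask over the defined points.
    """
    if y.size < 5:
        return np.ones(y.size, dtype=bool)
    from scipy.ndimage import median_filter

    med = median_filter(y, size=window, mode="nearest")
    resid = np.abs(y - med)
    dev = median_filter(resid, size=window, mode="nearest")
    scale = np.maximum(1.4826 * dev, 0.5)  # floor guards zero-MAD plateaus
    return resid <= n_mad * scale


def smoothing_spline_fill(
    columns: np.ndarray,
    values: np.ndarray,
    n_columns: int,
    smoothing_parameter: float = DEFAULT_SMOOTHING,
    reject_outliers: bool = True,
) -> np.ndarray:
    """Fit a smoothing spline to defined points and evaluate at every column."""
    if not 0 < smoothing_parameter < 1:
        raise ValueError("smoothing_parameter must lie in (0, 1)")
    keep = np.ones(values.size, dtype=bool)
    if reject_outliers:
        keep = _drop_outliers(columns, values)
    x, y = columns[keep].astype(float), values[keep].astype(float)
    if x.size < 4:
        raise InsufficientDataError(f"only {x.size} defined points; need at least 4 for spline fitting")
    lam = (1.0 - smoothing_parameter) / smoothing_parameter
    spline = make_smoothing_spline(x, y, lam=lam)
    return spline(np.arange(n_columns, dtype=float))


def smooth_trace(trace: WallTrace, smoothing_parameter: float = DEFAULT_SMOOTHING) -> WallTrace:
    """Smooth a wall trace and fill gaps/exclusions with a smoothing spline."""
    defined = trace.defined
    cols = np.flatnonzero(defined)
    filled = smoothing_spline_fill(
        cols, trace.rows[cols], trace.rows.size, smoothing_parameter
    )
    return replace(trace, rows=filled)


def diameter_waveform(
    near: WallTrace,
    far: WallTrace,
    value_cal: float,
    time_cal: float,
) -> RawWaveform:
    """Inner-edge-to-inner-edge diameter in cm from two gap-free wall traces."""
    if near.rows.size != far.rows.size:
        raise ValueError("near and far traces must have the same column count")
    if not (np.all(np.isfinite(near.rows)) and np.all(np.isfinite(far.rows))):
        raise ValueError("traces must be gap-free (smooth first)")
    sep = far.rows - near.rows
    if np.any(sep <= 0):
        bad = int(np.argmax(sep <= 0))
        raise AnatomyError(f"walls cross at column {bad}: far row <= near row")
    return RawWaveform(values=sep * value_cal, time_cal=time_cal, kind="diameter")


def trace_doppler_envelope(
    rec: UltrasoundRecording,
    threshold: float,
    start_column: int = 0,
    exclusions: Sequence[tuple[int, int]] = (),
    flow_side: str = "up",
    smoothing_parameter: float = DEFAULT_SMOOTHING,
) -> RawWaveform:
    """Trace the maximum Doppler envelope and return velocity in m/s.

    Per column (from ``start_column``), the envelope row is the
    suprathreshold row farthest from the baseline on the forward-flow side;
    velocity is ``|baseline_row - row| * value_cal``.  Missing and excluded
    columns are filled by the same smoothing-spline procedure used for the
    walls.
    """
    if rec.modality != "doppler":
        raise ValueError("recording must be a doppler acquisition")
    if rec.baseline_row is None:
        raise ValueError("doppler recording lacks baseline_row")
    if not (0 <= start_column < rec.n_columns):
        raise ValueError(f"start_column {start_column} outside image")
    if flow_side not in ("up", "down"):
        raise ValueError("flow_side must be 'up' or 'down'")
    baseline = int(rec.baseline_row)
    b0, b1 = rec.ecg_band
    if flow_side == "up":
        lo, hi = 0, baseline + 1
        if b1 <= baseline:  # ECG strip above baseline: keep it out of the search
            lo = b1
        sub = rec.pixels[lo:hi]
        mask = sub > threshold
        idx = lo + np.argmax(mask, axis=0)  # shallowest = farthest above baseline
    else:
        lo, hi = baseline, rec.pixels.shape[0]
        if b0 >= baseline:
            hi = min(hi, b0)
        sub = rec.pixels[lo:hi]
        mask = sub > threshold
        idx = (hi - 1) - np.argmax(mask[::-1], axis=0)
    any_hit = mask.any(axis=0)
    velocity = np.full(rec.n_columns, np.nan)
    velocity[any_hit] = np.abs(baseline - idx[any_hit]) * rec.value_cal
    velocity[:start_column] = np.nan
    _apply_exclusions(velocity, exclusions)
    span = rec.n_columns - start_column
    missing = np.mean(~np.isfinite(velocity[start_column:]))
    if span <= 0 or missing > MAX_MISSING_FRACTION:
        raise TracingQualityError(
            f"doppler envelope: {missing:.0%} of columns untraced; adjust threshold {threshold}"
        )
    cols = np.flatnonzero(np.isfinite(velocity))
    filled = smoothing_spline_fill(cols, velocity[cols], rec.n_columns, smoothing_parameter)
    return RawWaveform(values=filled, time_cal=rec.time_cal, kind="velocity")
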