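"""ECG strip extraction and R-peak detection.

The ECG is rendered as a bright trace inside a dedicated row band of the
concatenated image.  Per column, the trace row is taken as the
intensity-weighted centroid of suprathreshold pixels within the band, which
is robust to a 2-pixel-thick rendering.  Amplitude is measured in pixels
above the bottom of the band.  R-peaks are detected by threshold crossing at
a height-relative level (default 0.8 of the global min-to-max excursion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EcgExtractionError
from .image_io import UltrasoundRecording

__all__ = ["EcgTrace", "extract_ecg_trace", "detect_r_peaks"]

DEFAULT_THRESHOLD_FRACTION = 0.8
DEFAULT_REFRACTORY_MS = 200.0


@dataclass
class EcgTrace:
    """Per-column ECG amplitude (pixels above the strip baseline)."""

    amplitude: np.ndarray
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    r_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.r_peaks.size and np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")


def extract_ecg_trace(
    rec: UltrasoundRecording,
    intensity_floor: float | None = None,
    max_missing_fraction: float = 0.5,
) -> EcgTrace:
    """Extract the ECG amplitude from the recording's strip band.

    Columns where no pixel exceeds the intensity floor are filled by linear
    interpolation from neighbouring columns.  The floor defaults to 25% of
    the band's min-to-max intensity range above the minimum.

    Raises
    ------
    EcgExtractionError
        If more than ``max_missing_fraction`` of columns contain no
        suprathreshold pixel.
    """
    b0, b1 = rec.ecg_band
    if b1 - b0 < 3:
        raise EcgExtractionError(f"ecg_band {rec.ecg_band} has fewer than 3 rows")
    band = rec.pixels[b0:b1].astype(float)
    lo, hi = band.min(), band.max()
    if intensity_floor is None:
        intensity_floor = lo + 0.25 * (hi - lo)
    weights = band - intensity_floor
    weights[weights <= 0] = 0.0
    colsum = weights.sum(axis=0)
    defined = colsum > 0
    n_cols = band.shape[1]
    if defined.sum() < (1.0 - max_missing_fraction) * n_cols:
        raise EcgExtractionError(
            f"only {int(defined.sum())}/{n_cols} columns contain an ECG trace"
        )
    rows = np.full(n_cols, np.nan)
    idx_rows = np.arange(band.shape[0])[:, None]
    rows[defined] = (weights[:, defined] * idx_rows).sum(axis=0) / colsum[defined]
    # amplitude in pixels above the bottom row of the band
    amplitude = (band.shape[0] - 1) - rows
    cols = np.arange(n_cols)
    amplitude = np.interp(cols, cols[defined], amplitude[defined])
    return EcgTrace(amplitude=amplitude)


def detect_r_peaks(
    trace: EcgTrace,
    threshold_fraction: float | None = None,
    refractory_columns: int = 0,
) -> np.ndarray:
    """Detect R-wave peaks by upward threshold crossings.

    For each upward crossing of ``min + threshold_fraction * (max - min)``,
    the column of maximum amplitude between that crossing and the next
    downward crossing is returned.  Crossings closer than
    ``refractory_columns`` to the previously accepted peak are skipped.
    A trace with no crossings (e.g. constant amplitude) yields an empty
    result; the caller decides whether that is fatal.
    """
    a = trace.amplitude
    if a.size < 2:
        raise ValueError("trace must have at least 2 columns")
    frac = trace.threshold_fraction if threshold_fraction is None else threshold_fraction
    if not 0 < frac < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    lo, hi = float(a.min()), float(a.max())
    if hi - lo <= 0:
        return np.array([], dtype=int)
    thr = lo + frac * (hi - lo)
    above = a >= thr
    ups = np.flatnonzero(above & ~np.roll(above, 1))
    if above[0]:
        ups = np.union1d(ups, [0])
    peaks: list[int] = []
    for up in ups:
        if peaks and up - peaks[-1] < refractory_columns:
            continue
        down = up
        while down < a.size and above[down]:
            down += 1
        peaks.append(int(up + np.argmax(a[up:down])))
    return np.asarray(peaks, dtype=int)


def refractory_columns_from_ms(refractory_ms: float, time_cal_ms: float) -> int:
    """Convert a refractory period in milliseconds to pixel columns."""
    return max(0, int(round(refractory_ms / time_cal_ms)))
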