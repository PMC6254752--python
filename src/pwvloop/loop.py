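"""ln(D)U-loop construction, early-systolic fitting, and PWV conversion.

A diameter beat and a velocity beat are aligned at their detected upstroke
onsets, resampled onto a common uniform grid, and truncated at the tail so
both series have the length of the shorter (the diastolic portion is
sacrificed; the systolic slope is what matters).  The loop fit grows forward
from the common onset, adding one point at a time while the least-squares
line of U against ln(D) keeps r^2 above the threshold (default 0.98); the
wave speed is half the fitted slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import WaveformBeat
from .errors import DegenerateBeatError, NumericError

__all__ = ["LoopPair", "LoopFit", "align_and_truncate", "fit_loop", "pwv_from_slope"]

DEFAULT_DT = 0.001  # seconds
DEFAULT_FIT_R2 = 0.98
MIN_PAIR_SAMPLES = 10
MIN_FIT_POINTS = 3


@dataclass
class LoopPair:
    """Aligned, equal-length (ln D, U) series; sample 0 is the common onset."""

    lnD: np.ndarray
    U: np.ndarray
    dt: float
    d_source: tuple = ()
    u_source: tuple = ()

    def __post_init__(self) -> None:
        self.lnD = np.asarray(self.lnD, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        if self.lnD.shape != self.U.shape:
            raise ValueError("lnD and U must have identical length")
        if self.lnD.size < MIN_PAIR_SAMPLES:
            raise ValueError(f"loop pair needs >= {MIN_PAIR_SAMPLES} samples, got {self.lnD.size}")

    @property
    def n(self) -> int:
        return self.lnD.size


@dataclass
class LoopFit:
    """Early-systolic linear fit of one ln(D)U-loop."""

    slope: float | None
    r2: float | None
    n_fit: int
    pwv: float | None
    flags: list[str] = field(default_factory=list)
    d_source: tuple = ()
    u_source: tuple = ()

    @property
    def ok(self) -> bool:
        return not self.flags and self.pwv is not None


def _resample_from_onset(beat: WaveformBeat, dt: float) -> np.ndarray:
    """Beat values on a uniform grid of step ``dt`` from onset to closing R-peak."""
    t0 = beat.onset_time
    span = beat.duration - t0
    if span < MIN_PAIR_SAMPLES * dt:
        raise DegenerateBeatError(
            f"beat {beat.beat_index} (run {beat.run_id}): onset-to-R span {span:.3f}s "
            f"shorter than {MIN_PAIR_SAMPLES} samples at dt={dt}s"
        )
    n = int(np.floor(span / dt + 1e-9)) + 1
    grid = t0 + np.arange(n) * dt
    return np.interp(grid, beat.times, beat.values)


def align_and_truncate(
    d_beat: WaveformBeat, u_beat: WaveformBeat, dt: float = DEFAULT_DT
) -> LoopPair:
    """Align two beats at their upstroke onsets on a common grid.

    Each beat is linearly interpolated onto a uniform grid of step ``dt``
    starting at its own onset and ending at its closing R-peak; the longer
    series is then truncated at the tail to the length of the shorter.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if d_beat.onset_index is None or u_beat.onset_index is None:
        raise ValueError("both beats need a detected upstroke onset")
    d_vals = _resample_from_onset(d_beat, dt)
    u_vals = _resample_from_onset(u_beat, dt)
    n = min(d_vals.size, u_vals.size)
    return LoopPair(
        lnD=np.log(d_vals[:n]),
        U=u_vals[:n],
        dt=dt,
        d_source=(d_beat.run_id, d_beat.beat_index),
        u_source=(u_beat.run_id, u_beat.beat_index),
    )


def _prefix_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """r^2 of the OLS line of y on x for every prefix length 1..n (vectorized)."""
    n = np.arange(1, x.size + 1, dtype=float)
    sx, sy = np.cumsum(x), np.cumsum(y)
    sxx, syy, sxy = np.cumsum(x * x), np.cumsum(y * y), np.cumsum(x * y)
    den_x = n * sxx - sx * sx
    den_y = n * syy - sy * sy
    num = n * sxy - sx * sy
    scale = np.maximum(np.maximum(syy, sxx), 1.0)
    r2 = np.zeros(x.size)
    good = (den_x > 1e-12 * scale) & (den_y > 1e-12 * scale)
    r2[good] = num[good] ** 2 / (den_x[good] * den_y[good])
    r2[den_y <= 1e-12 * scale] = 1.0  # flat y: a horizontal line fits exactly
    return r2


def fit_loop(pair: LoopPair, r2_min: float = DEFAULT_FIT_R2) -> LoopFit:
    """Grow the early-systolic fit forward from the common onset.

    Starting from the first 3 samples, points are added one at a time; the
    first addition with ``r^2 <= r2_min`` stops the growth and the reported
    fit is the last one with ``r^2 > r2_min``.  A loop that never reaches 3
    points above the threshold is flagged ``unfittable`` and carries no PWV.
    """
    x, y = pair.lnD, pair.U
    r2 = _prefix_r2(x, y)
    lengths = np.arange(1, x.size + 1)
    eligible = lengths >= MIN_FIT_POINTS
    failing = eligible & (r2 <= r2_min)
    first_fail = int(np.argmax(failing)) if failing.any() else None
    n_fit = x.size if first_fail is None else first_fail  # last length before failure
    if n_fit < MIN_FIT_POINTS:
        return LoopFit(
            slope=None, r2=None, n_fit=0, pwv=None,
            flags=["unfittable"], d_source=pair.d_source, u_source=pair.u_source,
        )
    xf, yf = x[:n_fit], y[:n_fit]
    slope, _ = np.polyfit(xf, yf, 1)
    slope = float(slope)
    fit_r2 = float(_prefix_r2(xf, yf)[-1])
    pwv = pwv_from_slope(slope)
    flags = [] if pwv is not None else ["negative_slope"]
    return LoopFit(
        slope=slope, r2=fit_r2, n_fit=n_fit, pwv=pwv,
        flags=flags, d_source=pair.d_source, u_source=pair.u_source,
    )


def pwv_from_slope(slope: float) -> float | None:
    """Wave speed in m/s from a loop slope: ``pwv = slope / 2``.

    A non-positive slope means the loop cannot yield a forward wave speed;
    ``None`` is returned and the caller flags the loop.
    """
    if not np.isfinite(slope):
        raise NumericError(f"loop slope is not finite: {slope}")
    if slope <= 0:
        return None
    return slope / 2.0
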