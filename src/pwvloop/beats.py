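"""Beat segmentation, systolic upstroke-onset detection, and beat grouping.

The upstroke onset is found with a backward linear-regression search: start
at the temporal midpoint between the pre-peak minimum (the foot region) and
the beat maximum, then extend the candidate segment downward one sample at a
time; the first extension whose ordinary least-squares fit drops below the
r-squared threshold (default 0.985) stops the search and the preceding point
is the onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientBeatsError, OnsetDetectionError, SegmentationError
from .tracing import RawWaveform

__all__ = [
    "WaveformBeat",
    "BeatGroup",
    "segment_beats",
    "detect_upstroke_onset",
    "select_groups",
    "match_groups",
]

DEFAULT_UPSTROKE_R2 = 0.985
DEFAULT_GROUP_SIZE = 6


@dataclass
class WaveformBeat:
    """One cardiac cycle on a uniform time grid starting at its R-peak."""

    times: np.ndarray  # seconds from the opening R-peak
    values: np.ndarray  # cm (diameter) or m/s (velocity)
    kind: str
    duration: float  # R-to-R interval, seconds
    run_id: int | str = 1
    beat_index: int = 0
    onset_index: int | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    @property
    def onset_time(self) -> float:
        if self.onset_index is None:
            raise ValueError("onset not yet detected")
        return float(self.times[self.onset_index])


@dataclass
class BeatGroup:
    """A window of consecutive beats from one run."""

    beats: list[WaveformBeat]
    run_id: int | str
    start_beat_index: int
    mean_duration: float = 0.0

    def __post_init__(self) -> None:
        idx = [b.beat_index for b in self.beats]
        if any(j - i != 1 for i, j in zip(idx, idx[1:])):
            raise ValueError("group beats must be consecutive")
        self.mean_duration = float(np.mean([b.duration for b in self.beats]))

    def __len__(self) -> int:
        return len(self.beats)


def segment_beats(
    waveform: RawWaveform,
    r_peaks: np.ndarray,
    run_id: int | str = 1,
) -> list[WaveformBeat]:
    """Split a continuous waveform into beats delimited by R-peak columns.

    Beat ``i`` spans columns ``[peak_i, peak_{i+1})``; its duration is the
    full R-to-R interval, so ``duration == n_samples * sample_interval``.
    """
    peaks = np.asarray(r_peaks, dtype=int)
    if peaks.size < 2:
        raise SegmentationError(f"need at least 2 R-peaks to segment beats, got {peaks.size}")
    if np.any(np.diff(peaks) <= 0):
        raise SegmentationError("r_peaks must be strictly increasing")
    dt = waveform.time_cal / 1000.0  # seconds per column
    kind = waveform.kind
    beats = []
    for i in range(peaks.size - 1):
        a, b = peaks[i], peaks[i + 1]
        vals = waveform.values[a:b]
        beats.append(
            WaveformBeat(
                times=np.arange(b - a) * dt,
                values=vals,
                kind=kind,
                duration=(b - a) * dt,
                run_id=run_id,
                beat_index=i,
            )
        )
    return beats


def _segment_r2(t: np.ndarray, v: np.ndarray) -> float:
    """Ordinary coefficient of determination of the least-squares line.

    A segment with (numerically) zero value variance is fit perfectly by a
    horizontal line, so r^2 is taken as 1.
    """
    n = t.size
    st, sv = t.sum(), v.sum()
    stt = (t * t).sum()
    svv = (v * v).sum()
    stv = (t * v).sum()
    den_t = n * stt - st * st
    den_v = n * svv - sv * sv
    if den_v <= 1e-12 * max(svv, 1.0):
        return 1.0
    if den_t <= 0:
        return 0.0
    num = n * stv - st * sv
    return float(num * num / (den_t * den_v))


def detect_upstroke_onset(beat: WaveformBeat, r2_min: float = DEFAULT_UPSTROKE_R2) -> int:
    """Locate the onset of the early-systolic upstroke.

    With ``m`` the beat maximum, ``f`` the minimum on ``[0, m]`` and
    ``s = (f + m) // 2`` the temporal mid-systole, candidate segments
    ``[k, s]`` are evaluated for ``k = s - 1, s - 2, ...``; the first ``k``
    whose linear fit has ``r^2 < r2_min`` stops the search and the onset is
    ``k + 1``.  If no candidate fails, the onset is ``f``.

    Raises :class:`OnsetDetectionError` for beats with no upstroke
    (monotone decreasing or flat).
    """
    v = beat.values
    if v.size < 10:
        raise OnsetDetectionError(f"beat {beat.beat_index}: too few samples ({v.size})")
    m = int(np.argmax(v))
    f = int(np.argmin(v[: m + 1])) if m > 0 else 0
    if m == 0 or v[m] - v[f] <= 1e-12:
        raise OnsetDetectionError(f"beat {beat.beat_index}: no systolic upstroke found")
    s = (f + m) // 2
    t = beat.times
    for k in range(s - 1, -1, -1):
        if _segment_r2(t[k : s + 1], v[k : s + 1]) < r2_min:
            return k + 1
    return f


def select_groups(beats: list[WaveformBeat], group_size: int = DEFAULT_GROUP_SIZE) -> list[BeatGroup]:
    """All moving windows of ``group_size`` consecutive beats."""
    if group_size < 1:
        raise ValueError("group_size must be at least 1")
    if len(beats) < group_size:
        raise InsufficientBeatsError(
            f"need at least {group_size} beats, got {len(beats)}"
        )
    groups = []
    for i in range(len(beats) - group_size + 1):
        window = beats[i : i + group_size]
        groups.append(
            BeatGroup(beats=window, run_id=window[0].run_id, start_beat_index=window[0].beat_index)
        )
    return groups


def match_groups(
    d_groups: list[BeatGroup], u_groups: list[BeatGroup]
) -> tuple[BeatGroup, BeatGroup]:
    """Select the (D group, U group) pair with the closest mean cycle duration.

    Ties are broken by the earliest ``start_beat_index`` in D, then in U.
    """
    if not d_groups or not u_groups:
        raise ValueError("both group lists must be non-empty")
    d_sorted = sorted(d_groups, key=lambda g: g.start_beat_index)
    u_sorted = sorted(u_groups, key=lambda g: g.start_beat_index)
    best: tuple[BeatGroup, BeatGroup] | None = None
    best_diff = np.inf
    for d in d_sorted:
        for u in u_sorted:
            diff = abs(d.mean_duration - u.mean_duration)
            if diff < best_diff:
                best, best_diff = (d, u), diff
    assert best is not None
    return best


def longest_unflagged_run(beats: list[WaveformBeat]) -> list[WaveformBeat]:
    """Longest stretch of consecutive beats with no QC flags."""
    best: list[WaveformBeat] = []
    current: list[WaveformBeat] = []
    for b in beats:
        if b.flags:
            current = []
        else:
            current.append(b)
            if len(current) > len(best):
                best = current[:]
    return best
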