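import numpy as np
import pytest
from scipy import stats

from conftest import corner_ramp_beat, make_beat
from pwvloop.beats import (
    BeatGroup,
    detect_upstroke_onset,
    longest_unflagged_run,
    match_groups,
    segment_beats,
    select_groups,
)
from pwvloop.errors import InsufficientBeatsError, OnsetDetectionError, SegmentationError
from pwvloop.synthetic import SyntheticSubject, generate_run
from pwvloop.tracing import RawWaveform


def oracle_onset(beat, r2_min=0.985):
    """Independent brute force: scipy.linregress over every segment ending at s."""
    v = beat.values
    m = int(np.argmax(v))
    f = int(np.argmin(v[: m + 1]))
    s = (f + m) // 2
    for k in range(s - 1, -1, -1):
        r = stats.linregress(beat.times[k : s + 1], v[k : s + 1])
        if r.rvalue**2 < r2_min:
            return k + 1
    return f


def _waveform(values, time_cal=5.0, kind="diameter"):
    return RawWaveform(values=values, time_cal=time_cal, kind=kind)


class TestSegmentBeats:
    def test_seven_peaks_six_beats(self):
        wf = _waveform(np.linspace(2.0, 2.5, 700))
        peaks = np.arange(0, 700, 100)  # 7 peaks
        beats = segment_beats(wf, peaks)
        assert len(beats) == 6
        assert sum(b.values.size for b in beats) == 600  # no overlap, full span

    def test_two_peaks_duration(self):
        wf = _waveform(np.linspace(2.0, 2.5, 300), time_cal=3.5)
        beats = segment_beats(wf, np.array([10, 250]))
        assert len(beats) == 1
        assert beats[0].duration == pytest.approx(240 * 3.5e-3)

    def test_fewer_than_two_peaks(self):
        wf = _waveform(np.linspace(2.0, 2.5, 300))
        with pytest.raises(SegmentationError):
            segment_beats(wf, np.array([5]))

    def test_generator_boundaries_exact(self):
        run = generate_run(SyntheticSubject(seed=3, heart_rate_cv=0.05), 6, "diameter")
        wf = _waveform(run.values, time_cal=run.dt * 1000.0)
        beats = segment_beats(wf, run.r_peaks)
        assert len(beats) == 6
        for b, (a, bnd) in zip(beats, zip(run.r_peaks, run.r_peaks[1:])):
            assert b.values.size == bnd - a
            np.testing.assert_array_equal(b.values, run.values[a:bnd])

    def test_duration_consistency_invariant(self):
        wf = _waveform(np.linspace(2.0, 2.5, 500), time_cal=2.0)
        for b in segment_beats(wf, np.array([0, 120, 260, 499])):
            assert b.duration == pytest.approx(b.values.size * b.dt, abs=b.dt)


class TestDetectUpstrokeOnset:
    def test_corner_ramp_onset(self):
        beat = corner_ramp_beat()
        got = detect_upstroke_onset(beat)
        assert got == oracle_onset(beat)
        assert got in (50, 51)

    def test_default_threshold(self):
        import inspect

        assert inspect.signature(detect_upstroke_onset).parameters["r2_min"].default == 0.985

    def test_pure_ramp_returns_foot(self):
        v = 2.0 + 0.01 * np.arange(100)
        beat = make_beat(v)
        assert detect_upstroke_onset(beat) == 0  # f = argmin = 0, search exhausts

    def test_monotone_decreasing_errors(self):
        beat = make_beat(3.0 - 0.01 * np.arange(100))
        with pytest.raises(OnsetDetectionError):
            detect_upstroke_onset(beat)

    def test_flat_beat_errors(self):
        with pytest.raises(OnsetDetectionError):
            detect_upstroke_onset(make_beat(np.full(100, 2.6)))

    def test_onset_precedes_maximum(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            beat = _random_beat(rng)
            onset = detect_upstroke_onset(beat)
            assert 0 <= onset < int(np.argmax(beat.values))

    def test_oracle_equivalence_200_random_beats(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            beat = _random_beat(rng)
            assert detect_upstroke_onset(beat) == oracle_onset(beat)


def _random_beat(rng):
    """Random flat/ramp/decay beat with noise; always has an upstroke."""
    n = int(rng.integers(80, 300))
    foot = int(rng.integers(5, n // 3))
    rise = int(rng.integers(10, n // 3))
    base = rng.uniform(1.5, 3.0)
    amp = rng.uniform(0.1, 0.5)
    v = np.full(n, base)
    top = min(foot + rise, n - 1)
    v[foot:top] = base + amp * (np.arange(top - foot) / max(rise - 1, 1))
    v[top:] = v[top - 1] - 0.3 * amp * (np.arange(n - top) / max(n - top, 1))
    v += rng.normal(0, rng.uniform(0.0, 0.01), n)
    return make_beat(v, dt=0.004)


class TestGroups:
    def _beats(self, durations, run_id=1):
        out = []
        for i, d in enumerate(durations):
            n = max(int(d / 0.005), 12)
            v = 2.6 + 0.1 * np.sin(np.linspace(0, np.pi, n))
            out.append(make_beat(v, dt=d / n, run_id=run_id, beat_index=i))
        return out

    def test_ten_beats_five_groups(self):
        groups = select_groups(self._beats([0.8] * 10), 6)
        assert len(groups) == 5
        assert [g.start_beat_index for g in groups] == [0, 1, 2, 3, 4]

    def test_six_beats_one_group(self):
        assert len(select_groups(self._beats([0.8] * 6), 6)) == 1

    def test_five_beats_error(self):
        with pytest.raises(InsufficientBeatsError, match="5"):
            select_groups(self._beats([0.8] * 5), 6)

    def test_group_count_law(self):
        for n in range(6, 15):
            assert len(select_groups(self._beats([0.8] * n), 6)) == n - 5

    def test_mean_duration(self):
        groups = select_groups(self._beats([0.7, 0.8, 0.9, 1.0, 1.1, 1.2]), 6)
        assert groups[0].mean_duration == pytest.approx(0.95, abs=0.01)

    def test_non_consecutive_rejected(self):
        beats = self._beats([0.8] * 6)
        beats[3].beat_index = 9
        with pytest.raises(ValueError):
            BeatGroup(beats=beats, run_id=1, start_beat_index=0)


class TestMatchGroups:
    def _group(self, duration, start, run_id=1):
        n = 6
        beats = []
        for i in range(n):
            m = max(int(duration / 0.005), 12)
            v = 2.6 + 0.1 * np.sin(np.linspace(0, np.pi, m))
            beats.append(make_beat(v, dt=duration / m, run_id=run_id, beat_index=start + i))
        return BeatGroup(beats=beats, run_id=run_id, start_beat_index=start)

    def test_identical_durations_tie_break_first(self):
        d = [self._group(0.8, s) for s in (0, 1, 2)]
        u = [self._group(0.8, s, run_id=2) for s in (0, 1, 2)]
        sel_d, sel_u = match_groups(d, u)
        assert sel_d.start_beat_index == 0 and sel_u.start_beat_index == 0

    def test_closest_duration_pair(self):
        d = [self._group(0.80, 0), self._group(0.85, 1)]
        u = [self._group(0.86, 0, run_id=2), self._group(0.95, 1, run_id=2)]
        sel_d, sel_u = match_groups(d, u)
        assert sel_d.mean_duration == pytest.approx(0.85, abs=0.01)
        assert sel_u.mean_duration == pytest.approx(0.86, abs=0.01)

    def test_single_groups(self):
        d, u = [self._group(0.8, 0)], [self._group(0.9, 0, run_id=2)]
        assert match_groups(d, u) == (d[0], u[0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            match_groups([], [self._group(0.8, 0)])


class TestLongestUnflaggedRun:
    def test_picks_longest_stretch(self):
        beats = [make_beat(2.6 + 0.1 * np.sin(np.linspace(0, np.pi, 50)), beat_index=i) for i in range(8)]
        beats[2].flags.append("onset_failure")
        out = longest_unflagged_run(beats)
        assert [b.beat_index for b in out] == [3, 4, 5, 6, 7]
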