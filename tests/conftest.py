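import numpy as np
import pytest

from pwvloop.beats import WaveformBeat
from pwvloop.synthetic import NoiseModel, SyntheticSubject


@pytest.fixture
def quiet_subject():
    """Noiseless, reflection-free subject with fixed cycle length."""
    return SyntheticSubject(
        c_true=4.1, seed=11, reflection_magnitude=0.0, heart_rate_cv=0.0,
        noise=NoiseModel(pixel=0.0, waveform=0.0),
    )


@pytest.fixture
def noisy_subject():
    """Moderate pixel noise, reflections well after the upstroke onset."""
    return SyntheticSubject(
        c_true=4.1, seed=12, reflection_magnitude=0.15, reflection_delay=0.10,
        heart_rate_cv=0.03, noise=NoiseModel(pixel=6.0, waveform=0.0),
    )


def make_beat(values, dt=0.005, kind="diameter", onset_index=None, run_id=1, beat_index=0):
    values = np.asarray(values, dtype=float)
    return WaveformBeat(
        times=np.arange(values.size) * dt,
        values=values,
        kind=kind,
        duration=values.size * dt,
        run_id=run_id,
        beat_index=beat_index,
        onset_index=onset_index,
    )


def corner_ramp_beat():
    """Flat at 2.6 until sample 50, then a linear ramp to the max at 120.

    The ramp opens with a 2-step jump so the backward r-squared search
    stops right at the corner.
    """
    n = 200
    v = np.full(n, 2.6)
    i = np.arange(n)
    sel = (i > 50) & (i <= 120)
    v[sel] = 2.6 + 0.005 * (i[sel] - 50 + 2.0)
    v[i > 120] = v[120] - 0.002 * (i[i > 120] - 120)
    return make_beat(v)
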