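import numpy as np
import pytest

from mmn_rubberband.synth.epochs import default_t_axis
from mmn_rubberband.waveforms import MMNWave


@pytest.fixture(scope="session")
def t_axis():
    return default_t_axis()


def make_wave(samples, t_axis, subject_id=0, isi_s=1.5, channel="FZ"):
    return MMNWave(
        subject_id=subject_id,
        isi_s=isi_s,
        channel=channel,
        t_axis=t_axis,
        samples=np.asarray(samples, dtype=float),
    )


def linear_component(t_axis, amplitude, t_on, t_pk, t_off):
    """Sampled piecewise-linear dip: 0 → -amplitude → 0."""
    t = np.asarray(t_axis, dtype=float)
    v = np.zeros_like(t)
    rise = (t >= t_on) & (t <= t_pk)
    fall = (t > t_pk) & (t <= t_off)
    v[rise] = -amplitude * (t[rise] - t_on) / (t_pk - t_on)
    v[fall] = -amplitude * (t_off - t[fall]) / (t_off - t_pk)
    return v


@pytest.fixture
def linear_wave(t_axis):
    """The worked example: 0→-5 µV over 120→180 ms, back to 0 at 260 ms."""
    return make_wave(linear_component(t_axis, 5.0, 120.0, 180.0, 260.0), t_axis)
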