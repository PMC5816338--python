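import numpy as np
import pytest

from vvorkit import VelocityTrace


def make_sine_trace(
    duration=10.0, fs=220.0, freq=1.5, head_amp=150.0, gain=1.0, eye=None
) -> VelocityTrace:
    """Plain sinusoidal head trace with eye = -gain * head (or an override)."""
    t = np.arange(int(round(duration * fs))) / fs
    head = head_amp * np.sin(2 * np.pi * freq * t)
    if eye is None:
        eye = -gain * head
    return VelocityTrace(t=t, head_vel=head, eye_vel=eye, sample_rate=fs)


@pytest.fixture
def sine_trace():
    return make_sine_trace()
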