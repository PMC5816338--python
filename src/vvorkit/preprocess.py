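"""Window selection, sign conventions and median-filter desaccading.

The slow compensatory eye response in a VVOR recording is interrupted by
nystagmus fast phases (saccades).  Desaccading removes them with a running
median over a window of ``n`` samples: the median is robust to brief
high-velocity spikes but tracks the smooth sinusoidal response.  The window
is expressed in samples, so its temporal extent depends on the sampling
rate — at 220 Hz the default ``n = 30`` spans about 136 ms.

For even ``n`` the window is the asymmetric span ``[i - n/2, i + n/2 - 1]``
and the median of an even number of samples is the mean of the two middle
order statistics, matching the classic one-dimensional median filter of
signal-processing practice.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, TooShortError
from .trace_io import VelocityTrace

#: Seconds discarded at the start of each recording before windowing.
STARTUP_DISCARD_S = 1.0


@dataclass(frozen=True)
class DesaccadeParams:
    """Median-filter settings.

    n
        Window length in **samples** (not milliseconds); must be >= 3.
    edge_mode
        "zero" pads the signal with zeros beyond its ends (the behavior of
        the classic filter routine); "reflect" mirrors the signal instead and
        avoids the spurious edge residuals zero-padding creates.
    """

    n: int = 30
    edge_mode: str = "zero"

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ParameterError(f"median-filter window n must be >= 3, got {self.n}")
        if self.edge_mode not in ("zero", "reflect"):
            raise ParameterError(f"edge_mode must be 'zero' or 'reflect', got {self.edge_mode!r}")


@dataclass(frozen=True)
class SignConvention:
    """Channel polarity flags and direction labels.

    Some goggles record rightward head movement as negative velocity; the
    flags let the user normalize polarity.  Lateral labels ("rightward" /
    "leftward") should only be asserted when the device's laterality is
    known; the defaults stay direction-neutral.
    """

    invert_head: bool = False
    invert_eye: bool = False
    positive_label: str = "positive-direction"
    negative_label: str = "negative-direction"


@dataclass
class DesaccadedTrace:
    """A velocity trace plus its median-filtered eye channel.

    ``residual = eye_raw - eye_filtered`` isolates the fast-phase (saccadic)
    component that the filter removed.
    """

    base: VelocityTrace
    eye_filtered: np.ndarray
    residual: np.ndarray
    params: DesaccadeParams | None = None

    def __post_init__(self) -> None:
        self.eye_filtered = np.asarray(self.eye_filtered, dtype=float)
        self.residual = np.asarray(self.residual, dtype=float)
        n = len(self.base)
        if len(self.eye_filtered) != n or len(self.residual) != n:
            raise ParameterError("eye_filtered and residual must match the trace length")

    # convenience passthroughs
    @property
    def t(self) -> np.ndarray:
        return self.base.t

    @property
    def head_vel(self) -> np.ndarray:
        return self.base.head_vel

    @property
    def sample_rate(self) -> float:
        return self.base.sample_rate

    def __len__(self) -> int:
        return len(self.base)


def select_window(trace: VelocityTrace, duration: float = 10.0) -> VelocityTrace:
    """Select the analysis window: ``duration`` seconds after a 1-s lead-in.

    The first second of the recording is discarded (test start-up), then the
    first contiguous ``duration``-second span is kept and time stamps are
    re-based to start at 0.  If the recording is shorter than requested, the
    whole post-discard trace is returned with a warning.

    Raises :class:`TooShortError` for recordings under 2 s total.
    """
    if duration <= 0:
        raise ParameterError("window duration must be positive")
    if trace.duration < 2.0:
        raise TooShortError(
            f"recording spans only {trace.duration:.2f}s; at least 2s required")
    t0 = trace.t[0] + STARTUP_DISCARD_S
    mask = trace.t >= t0
    t, head, eye = trace.t[mask], trace.head_vel[mask], trace.eye_vel[mask]
    if t[-1] - t[0] < duration:
        warnings.warn(
            f"recording shorter than requested window ({t[-1] - t[0]:.2f}s "
            f"< {duration:g}s); using the full post-discard trace",
            stacklevel=2,
        )
    else:
        keep = t < t[0] + duration
        t, head, eye = t[keep], head[keep], eye[keep]
    return trace.replace(t=t - t[0], head_vel=head, eye_vel=eye)


def apply_sign_convention(trace: VelocityTrace, conv: SignConvention) -> VelocityTrace:
    """Apply channel inversions; labels propagate via the analysis config."""
    head = -trace.head_vel if conv.invert_head else trace.head_vel
    eye = -trace.eye_vel if conv.invert_eye else trace.eye_vel
    return trace.replace(head_vel=head, eye_vel=eye)


def _running_median(x: np.ndarray, n: int, edge_mode: str) -> np.ndarray:
    # window at index i spans [i - n//2, i + n - 1 - n//2]; for even n this is
    # the asymmetric [i - n/2, i + n/2 - 1], for odd n the centered window
    left = n // 2
    right = n - 1 - left
    if edge_mode == "zero":
        padded = np.pad(x, (left, right), mode="constant", constant_values=0.0)
    else:
        padded = np.pad(x, (left, right), mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, n)
    return np.median(windows, axis=-1)


def desaccade(trace: VelocityTrace, params: DesaccadeParams = DesaccadeParams()) -> DesaccadedTrace:
    """Desaccade the eye channel with a one-dimensional median filter.

    The head channel is untouched.  Returns the filtered trace together with
    the saccadic residual (raw minus filtered).

    Raises :class:`ParameterError` if the window exceeds the trace length.
    """
    if params.n > len(trace):
        raise ParameterError(
            f"median-filter window n={params.n} exceeds trace length {len(trace)}")
    eye_filtered = _running_median(trace.eye_vel, params.n, params.edge_mode)
    return DesaccadedTrace(
        base=trace,
        eye_filtered=eye_filtered,
        residual=trace.eye_vel - eye_filtered,
        params=params,
    )


def identity_desaccade(trace: VelocityTrace) -> DesaccadedTrace:
    """Wrap a trace as a :class:`DesaccadedTrace` without filtering.

    Useful when the eye channel is already saccade-free (e.g. analytic
    inputs) and the gain methods should see it untouched.
    """
    return DesaccadedTrace(
        base=trace,
        eye_filtered=trace.eye_vel.copy(),
        residual=np.zeros_like(trace.eye_vel),
        params=None,
    )
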