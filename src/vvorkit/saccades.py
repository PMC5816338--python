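"""Saccade (fast-phase) detection from the desaccading residual.

Subtracting the median-filtered eye velocity from the raw channel leaves the
fast phases the filter removed.  Saccades are local maxima of the absolute
residual above a velocity threshold, with a refractory separation between
events; when two candidates are closer than the separation, the larger one
survives.

The peak thresholds are physiological defaults, not device constants: fast
phases reach hundreds of deg/s while smooth-response residuals stay within a
few percent of the stimulus amplitude, and successive saccades are separated
by tens of milliseconds at least.  Both are configurable and are echoed in
the analysis report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import DependencyError, ParameterError
from .preprocess import DesaccadedTrace
from .spectral import SpectralResult
from .trace_io import VelocityTrace


@dataclass(frozen=True)
class SaccadeParams:
    """Detection thresholds.

    min_peak_height
        Minimum absolute residual velocity (deg/s) to count as a saccade.
    min_separation
        Minimum time between successive saccade peaks (s).
    detect_both_polarities
        Count leftward and rightward fast phases alike (detection runs on
        the absolute residual); polarity is recorded per event.
    """

    min_peak_height: float = 30.0
    min_separation: float = 0.05
    detect_both_polarities: bool = True

    def __post_init__(self) -> None:
        if self.min_peak_height <= 0:
            raise ParameterError("min_peak_height must be > 0")
        if self.min_separation <= 0:
            raise ParameterError("min_separation must be > 0")


@dataclass
class SaccadeSummary:
    """Detected fast-phase events and their rate metrics."""

    peak_times: np.ndarray
    peak_amplitudes: np.ndarray  # signed residual velocity at each peak
    total_count: int
    per_second: float
    per_cycle: float | None = None  # filled in by saccades_per_cycle


def detect_saccades(
    dtrace: DesaccadedTrace, params: SaccadeParams = SaccadeParams()
) -> SaccadeSummary:
    """Detect fast phases in the desaccading residual.

    ``per_second`` divides the count by the analyzed window duration
    (sample count times the median sampling interval).  Zero detections is a
    valid outcome, not an error.
    """
    residual = dtrace.residual
    signal = np.abs(residual) if params.detect_both_polarities else residual
    distance = max(1, int(round(params.min_separation * dtrace.sample_rate)))
    peaks, _ = find_peaks(signal, height=params.min_peak_height, distance=distance)
    if dtrace.params is not None:
        # the first/last half-window of the residual is a filter edge
        # transient (zero padding), not eye movement; never count it
        n = dtrace.params.n
        lo, hi = n // 2, len(dtrace) - (n - 1 - n // 2)
        peaks = peaks[(peaks >= lo) & (peaks < hi)]
    duration = len(dtrace) * dtrace.base.median_dt
    return SaccadeSummary(
        peak_times=dtrace.t[peaks],
        peak_amplitudes=residual[peaks],
        total_count=int(peaks.size),
        per_second=float(peaks.size / duration),
    )


def saccades_per_cycle(summary: SaccadeSummary, spectral: SpectralResult | None) -> SaccadeSummary:
    """Express the saccade rate per head-oscillation cycle.

    ``per_cycle = per_second / dominant_freq`` with the dominant frequency
    taken from the head-velocity spectrum.
    """
    if spectral is None:
        raise DependencyError("saccades_per_cycle requires a spectral result")
    if spectral.dominant_freq <= 0:
        raise DependencyError("dominant frequency must be positive")
    return dataclasses.replace(
        summary, per_cycle=summary.per_second / spectral.dominant_freq
    )


def peak_velocities(trace: VelocityTrace) -> tuple[float, float]:
    """Maximum absolute head and eye velocity (deg/s) over the window."""
    return (
        float(np.max(np.abs(trace.head_vel))),
        float(np.max(np.abs(trace.eye_vel))),
    )
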