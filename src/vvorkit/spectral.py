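"""FFT assessment of head-oscillation periodicity.

The dominant head-movement frequency defines the stimulation "cycle" used to
express saccades per cycle, and the spectrum itself is a quick visual check
of how periodic the examiner's manual oscillation was.

No taper is applied (rectangular window): only the location of the spectral
peak matters here and the stimulus tone dwarfs leakage.  Bin width is
``1/duration`` (no zero padding), so frequency-resolution statements are
exact.  The dominance search excludes the DC bin and, by default, everything
below 0.2 Hz so slow examiner drift cannot masquerade as the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TooShortError
from .trace_io import VelocityTrace

#: Minimum samples for a meaningful spectrum.
MIN_SAMPLES = 64

#: Default low-frequency cutoff (Hz) for the dominance search.
DRIFT_CUTOFF_HZ = 0.2


@dataclass
class SpectralResult:
    """One-sided amplitude spectra and the dominant head frequency."""

    freqs: np.ndarray
    head_amp: np.ndarray
    eye_amp: np.ndarray
    dominant_freq: float
    bin_width: float


def fft_spectrum(
    trace: VelocityTrace,
    eye: np.ndarray | None = None,
    min_freq: float = DRIFT_CUTOFF_HZ,
) -> SpectralResult:
    """One-sided amplitude spectrum (|DFT| * 2/N) of both velocity channels.

    ``eye`` optionally substitutes a desaccaded eye signal for the raw
    channel; the head channel carries no saccades, so the dominant frequency
    is the same either way.  The dominant frequency is the bin of maximal
    head amplitude at or above ``min_freq``; ties break toward the lowest
    frequency.

    Raises :class:`TooShortError` below ``MIN_SAMPLES`` samples.
    """
    n = len(trace)
    if n < MIN_SAMPLES:
        raise TooShortError(f"spectrum needs >= {MIN_SAMPLES} samples, got {n}")
    eye_sig = trace.eye_vel if eye is None else np.asarray(eye, dtype=float)
    if len(eye_sig) != n:
        raise TooShortError("substituted eye signal length mismatch")

    dt = trace.median_dt
    freqs = np.fft.rfftfreq(n, d=dt)
    head_amp = np.abs(np.fft.rfft(trace.head_vel)) * 2.0 / n
    eye_amp = np.abs(np.fft.rfft(eye_sig)) * 2.0 / n

    search = (freqs >= max(min_freq, freqs[1] * 0.5)) & (freqs > 0)
    if not search.any():
        raise TooShortError("no frequency bins above the drift cutoff")
    cand = np.flatnonzero(search)
    dominant = float(freqs[cand[np.argmax(head_amp[cand])]])  # argmax -> lowest tie

    return SpectralResult(
        freqs=freqs,
        head_amp=head_amp,
        eye_amp=eye_amp,
        dominant_freq=dominant,
        bin_width=float(freqs[1]),
    )
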