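"""Synthetic VVOR recordings with known ground truth.

The generator emulates the bedside VVOR protocol: an examiner oscillates the
patient's head sinusoidally at 1–2 Hz with peak velocity 150–200 deg/s while
the patient fixates an earth-fixed target.  The smooth eye response is
``-g * head`` with independent gains for the two head directions; nystagmus
fast phases are injected as brief Gaussian velocity pulses on the eye
channel, oriented in the catch-up direction (compensatory) when gain is
below 1 and in the backup direction when above.  White measurement noise is
added to the eye channel.

Presets mirror the four clinical phenotypes the method distinguishes —
healthy, bilateral vestibulopathy, unilateral hypofunction after vestibular
neurectomy, and CANVAS — with directional gains, saccade rates and
oscillation frequencies set to the corresponding group means.

Everything is reproducible from the seed, and the returned
:class:`GroundTruth` records the exact injected saccade times so detector
recovery can be asserted sample-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .trace_io import CsvDialect, DEFAULT_DIALECT, VelocityTrace

#: Keep pulse centers at least this far (s) from head-velocity zero crossings
#: so the injected count stays unambiguous after median filtering.
ZERO_CROSSING_MARGIN_S = 0.03

#: Minimum spacing between injected pulses within a half-cycle (s).
PULSE_SPACING_S = 0.1

#: Keep pulse centers at least this far (s) from the recording boundaries,
#: where median filtering is dominated by edge effects.
RECORDING_EDGE_MARGIN_S = 0.2


@dataclass(frozen=True)
class SynthParams:
    """Generator settings.

    duration: s; sample_rate: Hz; freq: head oscillation, Hz (protocol 1–2);
    peak_head_vel: deg/s (protocol 150–200); g_pos / g_neg: true directional
    gains; saccades_per_cycle: expected injected fast phases per oscillation
    cycle; saccade_amp: pulse peak, deg/s; saccade_width: pulse full width
    (~4 sigma), s; noise_sd: white-noise SD on the eye channel, deg/s;
    freq_jitter: SD of the log half-cycle-period perturbation (examiner
    irregularity); seed: RNG seed.
    """

    duration: float = 20.0
    sample_rate: float = 220.0
    freq: float = 1.5
    peak_head_vel: float = 150.0
    g_pos: float = 1.0
    g_neg: float = 1.0
    saccades_per_cycle: float = 0.0
    saccade_amp: float = 150.0
    saccade_width: float = 0.04
    noise_sd: float = 2.0
    freq_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration * self.freq < 5:
            raise ParameterError("need at least 5 oscillation cycles (duration * freq >= 5)")
        if self.sample_rate < 20 * self.freq:
            raise ParameterError("sample_rate must be >= 20 * freq")
        for name in ("peak_head_vel", "saccade_amp", "saccade_width", "noise_sd",
                     "saccades_per_cycle", "freq_jitter"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        for name in ("g_pos", "g_neg"):
            g = getattr(self, name)
            if not 0.0 <= g <= 1.2:
                raise ParameterError(f"{name} must be in [0, 1.2], got {g}")


@dataclass
class GroundTruth:
    """What the generator actually injected."""

    g_pos: float
    g_neg: float
    freq: float
    saccade_times: np.ndarray
    saccade_signs: np.ndarray
    saccade_count: int
    params: SynthParams


#: (g_pos, g_neg, saccades_per_cycle, freq) per clinical phenotype:
#: group means of the four study populations.
_PRESETS: dict[str, tuple[float, float, float, float]] = {
    "healthy": (1.00, 1.00, 0.0, 1.52),
    "bilateral": (0.84, 0.82, 3.0, 1.0),
    "unilateral": (0.85, 0.69, 2.0, 1.76),
    "canvas": (0.45, 0.40, 4.0, 1.35),
}


def preset(name: str, **overrides) -> SynthParams:
    """Generator settings for a clinical phenotype.

    ``name`` is one of "healthy", "bilateral", "unilateral", "canvas";
    keyword overrides (e.g. ``seed=7``) replace any other field.
    """
    try:
        g_pos, g_neg, spc, freq = _PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
    kwargs = {"g_pos": g_pos, "g_neg": g_neg, "saccades_per_cycle": spc, "freq": freq}
    kwargs.update(overrides)  # explicit overrides win over preset values
    return SynthParams(**kwargs)


def _half_cycle_bounds(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Cumulative half-cycle boundary times covering [0, duration]."""
    half = 1.0 / (2.0 * params.freq)
    bounds = [0.0]
    while bounds[-1] < params.duration:
        eps = rng.normal() * params.freq_jitter
        bounds.append(bounds[-1] + half * float(np.exp(eps)))
    return np.asarray(bounds)


def simulate_vvor(params: SynthParams) -> tuple[VelocityTrace, GroundTruth]:
    """Generate one synthetic VVOR recording plus its ground truth."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate

    bounds = _half_cycle_bounds(params, rng)
    # piecewise-linear phase: half-cycle k spans phase [k*pi, (k+1)*pi]
    k = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(bounds) - 2)
    frac = (t - bounds[k]) / (bounds[k + 1] - bounds[k])
    phase = np.pi * (k + frac)
    head = params.peak_head_vel * np.sin(phase)

    g_dir = np.where(head > 0, params.g_pos, params.g_neg)
    eye = -g_dir * head

    # inject fast phases half-cycle by half-cycle
    lam = params.saccades_per_cycle / 2.0
    base_count = int(np.floor(lam))
    frac_count = lam - base_count
    sigma = params.saccade_width / 4.0
    margin = ZERO_CROSSING_MARGIN_S + 2.0 * sigma
    times: list[float] = []
    signs: list[float] = []
    for j in range(len(bounds) - 1):
        c = base_count + int(rng.random() < frac_count)
        if c == 0:
            continue
        start, stop = bounds[j], min(bounds[j + 1], params.duration)
        lo = max(start + margin, RECORDING_EDGE_MARGIN_S)
        hi = min(stop - margin, params.duration - RECORDING_EDGE_MARGIN_S)
        if hi <= lo:
            continue
        span = hi - lo
        jitter_amp = min(0.01, span / (8.0 * c))
        head_sign = 1.0 if j % 2 == 0 else -1.0
        g_here = params.g_pos if head_sign > 0 else params.g_neg
        pulse_sign = -head_sign if g_here <= 1.0 else head_sign
        for m in range(c):
            center = lo + (m + 0.5) * span / c + rng.uniform(-jitter_amp, jitter_amp)
            times.append(float(center))
            signs.append(pulse_sign)
    times_arr = np.asarray(times)
    signs_arr = np.asarray(signs)
    for center, sign in zip(times_arr, signs_arr):
        eye = eye + sign * params.saccade_amp * np.exp(-((t - center) ** 2) / (2 * sigma**2))

    eye = eye + rng.normal(0.0, 1.0, n) * params.noise_sd

    trace = VelocityTrace(
        t=t, head_vel=head, eye_vel=eye, sample_rate=params.sample_rate,
        source=f"synthetic(seed={params.seed}, f={params.freq}Hz, "
               f"g+={params.g_pos}, g-={params.g_neg})",
    )
    truth = GroundTruth(
        g_pos=params.g_pos, g_neg=params.g_neg, freq=params.freq,
        saccade_times=times_arr, saccade_signs=signs_arr,
        saccade_count=len(times_arr), params=params,
    )
    return trace, truth


def write_fixture_csv(
    traces: VelocityTrace | list[VelocityTrace],
    path: str | Path,
    dialect: CsvDialect = DEFAULT_DIALECT,
    float_fmt: str = "%.6f",
) -> None:
    """Write one or more traces as a CSV readable by ``read_vvor_csv``.

    Multiple traces become consecutive test blocks; this requires a
    ``test_marker`` column in the dialect (block ids "1", "2", ...).
    Requires named (string) columns.
    """
    if isinstance(traces, VelocityTrace):
        traces = [traces]
    cols = [dialect.column_time, dialect.column_head, dialect.column_eye]
    if not all(isinstance(c, str) for c in cols):
        raise ParameterError("write_fixture_csv requires named (string) columns")
    if len(traces) > 1 and dialect.test_marker is None:
        raise ParameterError("multiple blocks require a test_marker column in the dialect")

    def fmt(x: float) -> str:
        s = float_fmt % x
        return s.replace(".", dialect.decimal_mark) if dialect.decimal_mark != "." else s

    header = list(cols)
    if dialect.test_marker is not None:
        header.append(str(dialect.test_marker))
    lines = [dialect.delimiter.join(header)]
    for block_id, tr in enumerate(traces, start=1):
        for ti, hi, ei in zip(tr.t, tr.head_vel, tr.eye_vel):
            row = [fmt(ti), fmt(hi), fmt(ei)]
            if dialect.test_marker is not None:
                row.append(str(block_id))
            lines.append(dialect.delimiter.join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
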