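# Methods notes

## Signal model and assumptions

The analysis treats a VVOR recording as three aligned series: time stamps
(s), head angular velocity and eye angular velocity (°/s), sampled
near-uniformly (nominally 220 Hz; the device rate is configuration, not a
fixed fact — the reader estimates it from the median inter-sample interval
and requires it within 20% of the nominal). The eye channel is modelled as a
smooth compensatory component `−g·head` (with direction-specific gain) plus
brief fast-phase pulses plus measurement noise. All methods assume the head
channel is saccade-free, which holds for gyroscope-measured head velocity.

Analysis runs on a 10-s window taken after discarding the first second of
the recording (test start-up transients). Windowing precedes filtering: the
filter's edge handling is explicit, so filtering the shorter segment costs
nothing in correctness and the window boundaries are then the only edges to
reason about.

## Desaccading

A running median of `n` samples (default 30) over the eye channel. For even
`n` the window is the asymmetric span `[i − n/2, i + n/2 − 1]` and the
median of an even count is the mean of the two middle order statistics —
both fixed for bit-reproducibility and to match the classic 1-D median
filter. Implemented directly over `numpy` sliding windows because
`scipy.ndimage.median_filter` takes a single order statistic for even
windows, which is a different (biased) estimator.

Edge handling defaults to zero padding (the classic routine's behavior);
`reflect` is available and is free of the large artificial residual the zero
pad creates in the first/last half-window.

Two systematic effects are worth knowing:

* **Peak flattening.** The median of a sinusoid over a window spanning phase
  `±a` is `A·cos(a/2)`, so the filtered peak is low by `A·(1 − cos(a/2))`
  with `a = π·f·n/fs`. At 220 Hz / 1.5 Hz / n = 30 that is ≈ 5% of the
  amplitude, and it biases measured gains down by ~1–1.5% (visible in the
  healthy-preset mean gain of ≈ 0.99 rather than 1.00). The effect grows
  quickly with `f·n/fs`; at 100 Hz sampling a 30-sample window is already
  30% of a 1 Hz half-cycle and the filter visibly clips the response. `n` is
  in samples deliberately, but its temporal meaning depends on the sampling
  rate — re-tune it if your device is far from 220 Hz.
* **Edge transients.** With zero padding, the filtered output in the
  first/last half-window is pulled toward zero, leaving a residual of up to
  half the signal amplitude there. The saccade detector therefore never
  counts peaks inside the edge-transient region (first/last `n/2` samples);
  without this guard every trace would report ≥ 1 spurious saccade.

## Directional gains

Samples are split by the sign of head velocity; exact zeros carry no
directional label and belong to neither subset, and runs shorter than 2
samples are discarded. AUC integration is trapezoidal per contiguous run
with the real time stamps — integrating a concatenated subset would
fabricate trapezoids across run boundaries. The signed run integrals are
summed per channel and the gain is `−Σeye/Σhead`; the slope method fits
`eye = slope·head` without intercept (the single-column linear solve) and
returns `−slope`. One global negation makes compensatory responses positive;
anti-compensatory responses come out negative and are never clipped or
absolute-valued, since their sign is clinically meaningful (backup
saccades / inverted responses).

Both estimators are exactly invariant to scaling both channels and agree to
better than 1e−10 relative on any noiseless linear response, which the test
suite pins.

## Spectrum and saccade metrics

The amplitude spectrum is `|rfft|·2/N` on a rectangular window, bin width
`1/duration` (no zero padding), so "within one bin" statements in tests are
honest. Only the argmax matters, so spectral leakage is acceptable. The
dominance search excludes DC and bins below 0.2 Hz (slow examiner drift).

Saccade detection runs `scipy.signal.find_peaks` on |residual| with a height
threshold (default 30 °/s) and a refractory separation (default 50 ms);
when two candidates collide, the larger survives. The thresholds are
physiological defaults, not device facts — fast phases far exceed the ~5%
smooth-response residual at these stimulus amplitudes, and both values are
configurable and echoed in every report. `per_second` uses the analyzed
window duration (sample count × median interval); `per_cycle` divides by
the FFT dominant frequency.

## Concordance

ICC form: two-way random effects, absolute agreement, single measure —
ICC(2,1) — computed from the subjects × methods ANOVA mean squares, with
the McGraw–Wong F-based 95% CI (Satterthwaite df). Absolute agreement is the
right form because the question is whether the two gain methods are
interchangeable, not merely correlated. The paired unit is one
subject-direction (positive and negative gains enter as separate pairs).
Degenerate inputs: fewer than 3 pairs and zero total variance raise typed
errors; perfect agreement returns ICC = 1 with a collapsed CI. Bland–Altman
limits are `bias ± 1.96·SD` (sample SD, ddof = 1).

## Synthetic generator

`simulate_vvor` emulates the manual protocol: sinusoidal head velocity
(default 1.5 Hz, 150 °/s peak, 20 s at 220 Hz), optional log-normal
half-cycle period jitter for examiner irregularity (default 0 — the test
batteries isolate measurement noise as the stochastic ingredient), smooth
eye response `−g_dir·head`, Gaussian fast-phase pulses (amplitude 150 °/s,
full width 40 ms ≈ 4σ) oriented in the catch-up direction for gain < 1 and
the backup direction for gain > 1, and white noise on the eye channel
(default SD 2 °/s, a realistic video-oculography noise floor). Pulse counts
per half-cycle are `floor(rate/2)` plus a Bernoulli remainder, so the
configured saccades/cycle is matched in expectation with low variance and
injected counts can be recovered exactly; pulses are kept ≥ 30 ms from
head-velocity zero crossings and ≥ 200 ms from the recording boundaries so
ground truth stays unambiguous after filtering. Presets set (g⁺, g⁻,
saccades/cycle, f) to the four phenotype group means: healthy (1.00, 1.00,
0, 1.52 Hz), bilateral (0.84, 0.82, 3, 1.0 Hz), unilateral (0.85, 0.69, 2,
1.76 Hz), CANVAS (0.45, 0.40, 4, 1.35 Hz).

What the generator does **not** model: eye-plant dynamics and saccade main
sequence, blink/pupil-tracking artifacts, goggle slippage, optokinetic and
cervico-ocular contributions, and non-sinusoidal head waveforms. Passing
tests therefore demonstrate correctness of the numerical pipeline and
recoverability of known parameters under idealized phenomenology — not
clinical validity on device data.

## Problem sizes

Test batteries use 20-s traces at 220 Hz (4,400 samples; 2,200 analyzed),
25–50 replicates per preset for recovery checks, and a 35-trace
four-phenotype battery (70 directional gain pairs) for concordance — sizes
chosen to keep Monte-Carlo error well below the asserted tolerances while
the whole suite runs in seconds.

## Known limitations

* Gain estimates carry the ~1% median-filter flattening bias described
  above; it is common to both methods, so concordance statistics do not see
  it.
* The CSV reader assumes one header row when columns are named; vendor
  binary/session formats are out of scope.
* The ICC CI is asymptotic (F-based); for very small batteries (< 6 pairs)
  it is wide and approximate.
* Saccade detection counts events only; kinematics (amplitude in degrees,
  latency, overt/covert classification) are out of scope.
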