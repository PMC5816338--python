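# vvorkit

Automated analysis of **visually enhanced vestibulo–ocular reflex (VVOR)**
recordings from video head-impulse (vHIT) goggles.

During a VVOR test the examiner oscillates the patient's head sinusoidally at
1–2 Hz (peak velocity 150–200 °/s) while the patient fixates an earth-fixed
target. A healthy oculomotor system rotates the eyes opposite to the head with
**gain** ≈ 1 (gain = compensatory eye velocity / head velocity). Vestibular and
cerebellar disease lowers the gain and fills the trace with catch-up saccades.
`vvorkit` turns a raw CSV export of such a recording into directional gains and
saccade metrics, for clinicians and researchers who want numbers instead of a
visual read of the trace.

## Method

Given time-aligned head and eye angular-velocity samples, the pipeline:

1. selects a 10-s analysis window (after discarding the first second);
2. **desaccades** the eye channel with a one-dimensional median filter of
   window length *n* = 30 samples,
   `y(i) = median x[i − n/2 : i + n/2 − 1]` — the running median rejects the
   brief fast-phase spikes but follows the smooth sinusoidal response;
3. splits samples by head-velocity sign into positive- and negative-direction
   runs and computes gain two ways per direction:
   * **AUC**: `G_AUC = −(Σ ∫eye dt) / (Σ ∫head dt)` with trapezoidal
     integration run by run;
   * **SCP**: the no-intercept least-squares slope of eye on head velocity,
     `G_SP = −Σ(h·e)/Σ(h²)`;

   compensatory responses give positive gain; anti-compensatory responses give
   negative gain and are reported as such, never clipped;
4. estimates the head-oscillation frequency as the dominant bin of the
   head-velocity amplitude spectrum (FFT, rectangular window);
5. detects saccades as peaks of the |raw − desaccaded| residual above 30 °/s
   with ≥ 50 ms separation and reports the count, saccades/s and
   saccades/cycle (rate ÷ dominant frequency);
6. measures agreement between the two gain methods with the intra-class
   correlation coefficient ICC(2,1) (≥ 0.90 read as excellent concordance)
   and Bland–Altman bias / limits of agreement.

A synthetic trace generator (`vvorkit.synth`) produces ground-truthed
recordings with presets mirroring four clinical phenotypes — healthy,
bilateral vestibulopathy, unilateral hypofunction and CANVAS — so the whole
pipeline is testable without device data.

## Worked example

```sh
$ vvorkit simulate --preset unilateral --seed 7 --out vvor_uni.csv --truth truth.json
wrote vvor_uni.csv (unilateral, seed 7, 70 injected saccades)
$ vvorkit analyze vvor_uni.csv -o report.json
G_AUCp 0.837  G_AUCn 0.677
G_SPp  0.834  G_SPn  0.673
dominant frequency 1.80 Hz
saccades 34 (3.40/s, 1.89/cycle)
peak head 150.0 deg/s, peak eye 278.5 deg/s
```

The simulated patient has true directional gains 0.85 / 0.69 (the asymmetry of
a unilateral vestibular lesion: the deficient side is the negative direction
here) and 2 injected catch-up saccades per cycle. Both gain methods recover
the asymmetry to within a few hundredths of the truth and agree with each
other to ≤ 0.005; the detector finds the ~2 saccades/cycle within the 10-s
analysis window; the 1.76 Hz stimulation frequency is read off the spectrum at
the 0.1 Hz bin resolution. `report.json` holds the same numbers plus the full
parameter audit trail.

The library API mirrors the CLI:

```python
from vvorkit import preset, simulate_vvor, select_window, desaccade, auc_gain

trace, truth = simulate_vvor(preset("canvas", seed=1))
g = auc_gain(desaccade(select_window(trace)))
print(g.g_pos, g.g_neg)   # ~0.45, ~0.40
```

Paired gains from two methods can be checked for interchangeability with
`vvorkit agree pairs.csv` (ICC + Bland–Altman block).

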