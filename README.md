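# erplat

**ERP latency analysis for orientation-contrast (pop-out) experiments, with
synthetic-EEG parameter recovery.**

`erplat` is a tested, reusable implementation of the analysis chain used to
ask *when* the visual system detects an orientation contrast — a small patch
of line segments orthogonal to a homogeneous texture background — relative
to the earliest cortical response, the C1 component. The C1 (peaking near
80 ms, negative for upper-visual-field and positive for lower-visual-field
stimuli at midline occipital electrodes) indexes the initial feedforward
volley in early visual cortex; if the pop-out signal arises later than the
C1 evoked by an abrupt onset at the same location, automatic contrast
detection cannot be a purely feedforward V1 phenomenon. The package is
aimed at EEG/ERP researchers who want the latency statistics themselves —
onset detection and jackknife peak-latency comparison — as well-tested
library functions, plus a simulator to validate them by parameter recovery.

## What it does

- **Synthetic EEG** (`erplat.synth`): multi-subject, multi-trial epochs with
  planted ERP components (asymmetric-Gaussian deflections with per-site gain
  maps), white + 1/f + alpha-band noise, per-subject latency/amplitude
  variability, amplitude artifacts; plus texture-stimulus geometry tables
  and simulated fixation-task behavior streams.
- **Preprocessing** (`erplat.preprocess`): mastoid re-referencing; zero-phase
  Blackman windowed-sinc low-pass (half-amplitude cutoff 40 Hz, transition
  band 20 Hz); first-order Butterworth high-pass applied forward–backward
  (half-amplitude 0.1 Hz); epoching on a half-open [−200, 600) ms window;
  ±70 μV amplitude rejection and ±650 ms button-press exclusion; 100-ms
  pre-stimulus baseline correction.
- **ERP core** (`erplat.erp`): trial-weighted condition averaging and
  pooling, grand averages, difference waves (contrast-minus-homogeneous
  "contrast effects", UVF-minus-LVF waves), half-open-window mean amplitudes.
- **Statistics** (`erplat.stats`): one-sample/paired/independent t, one-way
  ANOVA; sliding-window t-tests (20-ms windows, 2-ms steps, labelled by
  nominal midpoints) with the consecutive-significance onset rule (first
  window opening a run of ≥ 5 windows with p < .05); signed peak latency;
  and the jackknife latency-difference procedure with its corrected
  t-statistic.
- **Behavior** (`erplat.behavior`): luminance-detection hit/RT scoring with
  a (200, 1200] ms eligibility window, the ±10-step adaptive target-luminance
  rule, awareness-test accuracy.
- **Pipeline + CLI** (`erplat.pipeline`, `erplat` command): end-to-end
  experiment analyses on synthetic or containerized data, JSON reports with
  config-hash provenance.

## The statistics at the core

**Onset latency.** For a difference wave measured per subject at site *s*,
window means over 20-ms windows sliding in 2-ms steps are tested against
zero (t-test across subjects, two-sided, α = .05). The onset is the midpoint
of the first window that opens a run of at least *k* = 5 consecutive
significant windows.

**Jackknife peak-latency difference.** With per-subject waveforms for two
components, the latency difference `D = L_A − L_B` is measured on the grand
averages using the maximum-amplitude criterion (signed extremum in a search
window). Each subject is left out in turn and the difference recomputed on
the leave-one-out grand averages, giving `D_−i`; then

    se_jack = sqrt( (n−1)/n · Σ_i (D_−i − mean(D_−i))² ),   t = D / se_jack

with df = n − 1 (paired) or the two-group analogue with df = n₁ + n₂ − 2
(independent). The (n−1)/n inflation undoes the variance shrinkage that
leave-one-out grand averaging introduces; for a linear statistic the
jackknife SE reduces exactly to the classical SEM.

## Worked example

Recover a planted latency difference at full study scale (24 subjects,
576 trials/condition, one midline occipital site). The generator plants a
C1-like component peaking at 80 ms and a delayed contrast effect with onset
68 ms and peak 92 ms; the analysis recovers the onset and the ~12-ms peak
delay:

```python
from erplat.recovery import recovery_replicate

o = recovery_replicate(seed=3)
print(round(o.D_ms, 2), o.t_corrected, o.p, o.onset_ms)
# 11.72 inf 0.0 72.0
```

The jackknife latency difference is 11.7 ms (planted: 12 ms) and the
detected onset 72 ms (planted: 68 ms — the statistical onset trails the
true departure from zero because the effect is still tiny there). At this
signal-to-noise ratio the leave-one-out latencies are often identical at
the 512-Hz sample grid, so the jackknife SE is 0 and the corrected t
degenerates to infinity (reported p = 0); seeds with more latency
variability give finite t, e.g. seed 2 → D = 9.8 ms, t(23) = 2.15, p = .042.

The same inference runs end-to-end (trial-level simulation, filtering,
artifact rejection, baselining, averaging, statistics) from the shell:

```bash
erplat analyze --experiment exp1_contrast --seed 7 --subjects 12 --trials 192 \
               --report report.json
erplat report report.json
```

which prints, among other rows:

```
  homogeneous              POz [50,70) ms  -0.159 uV  t(11)=-3.394 p=0.0060
  onset LVF_contrast_effect    POz  80 ms
  jackknife LVF_contrast_vs_C1 D=+19.5 ms  t(11)=6.12 p=0.0001
```

— the whole-texture C1 is reliably negative in the 50–70 ms window, while
the contrast effect emerges only later and its peak trails the C1 peak
significantly. (At this reduced cohort size the point estimates are noisy;
the 24-subject replicate study above is the calibrated regime.)

`erplat simulate --out dir/` writes per-subject epoch containers (JSON
sidecar + little-endian float32 binary) and behavior-event TSVs that
`erplat analyze --data dir/` consumes.

## Layout

```
src/erplat/
  containers.py   # EventTable, ContinuousRecording, Epochs, ERPWaveform
  synth.py        # stimulus geometry, planted components, noise, behavior
  preprocess.py   # reference, filters, epoching, rejection, baseline
  erp.py          # averaging, pooling, difference waves, window means
  stats.py        # t/ANOVA, sliding-window onsets, jackknife latencies
  behavior.py     # detection scoring, staircase, awareness accuracy
  recovery.py     # replicate studies (parameter recovery, null calibration)
  pipeline.py     # experiment orchestration and reports
  io.py           # epochs container, optional EDF import
  cli.py          # erplat simulate / preprocess / analyze / report
docs/methods.md   # model, assumptions, calibration, limitations
```
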