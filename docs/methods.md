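# Methods

This note documents the models, conventions and calibrations behind
`erplat`: what the synthetic generator emulates (and what it does not),
the numerical choices in preprocessing and statistics, and the design
decisions taken where the underlying analysis convention is genuinely open.

## 1. The scientific procedure being implemented

The package times the ERP signature of automatic orientation-contrast
detection against the C1 component. The measurement chain is:

1. average artifact-free epochs per condition and subject;
2. form the *contrast effect* — the difference wave between a texture
   containing an orientation-contrast patch and the matched homogeneous
   texture (shared stimulus-evoked activity cancels, leaving the response
   attributable to the contrast itself);
3. estimate the effect's **onset** with sliding-window t-tests
   (20-ms windows, 2-ms steps, across-subject one-sample t against 0;
   onset = midpoint of the first window opening ≥ 5 consecutive windows
   with p < .05, two-sided);
4. compare **peak latencies** of the contrast effect and of the C1 evoked
   by abrupt-onset stimuli at the same retinal locations, using the
   leave-one-subject-out jackknife with the corrected t = D / se_jack,
   se_jack² = ((n−1)/n)·Σ(D₋ᵢ − D̄₋)². For independent groups the two
   per-group sums are added with their own (n_g−1)/n_g factors and
   df = n₁ + n₂ − 2. The (n−1)/n inflation compensates the n-fold variance
   shrinkage of leave-one-out grand averages; the implementation is
   unit-tested against exhaustive leave-one-out enumeration and against the
   exact SEM identity for linear statistics.

## 2. Synthetic data model

**Components.** A planted component is an asymmetric Gaussian truncated at
its onset: zero before `onset_ms`, then `(g(t) − g(onset))/(1 − g(onset))`
scaled by the signed amplitude, where g has SD `rise_sd` before the peak
(default `(peak − onset)/2.5`, so the onset sits 2.5 rise-SDs early and the
waveform leaves zero continuously) and `fall_sd = 1.4·rise_sd` after.
Scalp topography is a direct per-site gain map in [−1, 1]; no dipole
forward model (deliberately — the statistics operate on channel data and
do not care how the topography arose).

Canonical planted values: whole-texture C1-like response −0.8 μV peaking at
80 ms (onset 50 ms) with a midline parieto-occipital maximum; abrupt-onset
C1 −0.6 μV (UVF) / +0.5 μV (LVF), peak 80 ms; lower-field contrast effect
+0.6 μV, onset 68 ms, peak 92 ms, central posterior maximum; upper-field
contrast effect +0.4 μV, onset 88 ms, peak 97 ms, more lateral-occipital.
These place the planted latency difference between contrast-effect and C1
peaks at 12 ms in the lower field. Amplitudes are window-mean-scale
realistic for this paradigm (a few tenths of a microvolt).

**Noise.** Per trial: white Gaussian noise, FFT-shaped 1/f ("pink") noise,
and a fixed-frequency 10-Hz sinusoid with per-trial random phase (so it
attenuates as 1/√n in trial averages, like ongoing alpha). Per subject:
one latency shift (SD 3 ms) and one additive amplitude offset (SD 0.08 μV)
per *component* — a subject's C1 is one physiological response, so a
component shared between conditions receives identical perturbations in
each and cancels exactly in within-subject difference waves. Artifact
trials (rate 0.02) receive a 100-ms, 120-μV square pulse on one random
channel, which the ±70 μV rejection rule removes.

**Trial-averaging fast path.** Replicate studies use
`simulate_subject_erp`, which draws the subject *average* directly:
white/pink residuals at SD/√n with the same spectra (exact), and the alpha
resultant as a complex-normal sum (the CLT limit of n random phasors,
excellent for n ≥ a few tens). This is distributionally equivalent to
averaging n simulated artifact-free trials and keeps 300 replicates of a
24 × 576-trial study under a minute. The equivalence is tested (noiseless
equality; 1/√n residual scaling).

**Noise calibration.** Single-trial SDs default to white 3 / pink 2.5 /
alpha 1.5 μV. At 576 trials per condition and n = 24 subjects this puts
the across-subject SEM of 20-ms window means of the *difference wave* near
0.03–0.05 μV — a deliberately clean recording, roughly 2–4× cleaner than
is typical for this paradigm. The calibration target is recoverability of
the planted latencies: onset-latency recovery to ±6 ms demands a higher
SNR than amplitude significance, because the statistical onset (first
sustained significance) trails the true departure from zero by however
long the ramp stays below ~2 SEMs. With these defaults the detected onset
concentrates at 70–74 ms for a 68-ms planted onset. Consequences of the
idealization: single-replicate t-values run larger than typical published
values, and leave-one-out latencies are often identical at the sample
grid, driving the jackknife t to infinity (se_jack = 0 with D ≠ 0 is
reported as a signed infinite statistic, p = 0).

**What the generator does not emulate.** Ocular and myogenic artifact
morphology (artifacts are square pulses), non-stationary alpha bursts,
volume-conduction-consistent topographies, overlapping responses from
preceding stimuli, and electrode drift. Passing recovery tests therefore
show that the *statistics* recover planted parameters under plausible
noise — not that the pipeline is robust to every pathology of real EEG.

## 3. Preprocessing conventions

- **Filters.** Low-pass: Blackman windowed-sinc FIR, half-amplitude
  (−6 dB) cutoff 40 Hz, transition band 20 Hz; tap count
  `ceil(5.5·fs/Δf)` rounded up to odd (the Blackman window's normalized
  transition width), unit DC gain; applied once with group-delay
  compensation and reflection padding (zero phase, length-preserving).
  High-pass: first-order Butterworth with corner = half-amplitude point
  0.1 Hz, applied forward–backward; two passes square the magnitude, so
  the −3 dB corner of one pass is exactly the −6 dB (half-amplitude)
  point of the combined filter. Zero-phase application is the offline
  convention; phase handling is otherwise an open choice and is recorded
  here as such. Measured contracts: |H(40)| = 0.500 ± 0.01, |H(0)| = 1,
  |H(50)| < 0.01 for the FIR; |H(0.1)| = 0.5 ± 0.02, 10-Hz gain ≥ 0.999
  for the high-pass.
- **Epochs.** Half-open [−200, 600) ms; a sample belongs to the epoch iff
  −200 ≤ 1000·k/fs < 600, giving 400 samples at 500 Hz and 410 at 512 Hz;
  t = 0 is the first sample at/after the event time (no interpolation).
  Events too close to the recording edge yield flagged (`edge`) epochs,
  not silent drops.
- **Rejection.** A trial is rejected if |v| *strictly* exceeds 70 μV on
  any non-reference channel (a sample at exactly 70.0 μV is kept), or if
  its stimulus onset lies within the inclusive ±650 ms of a button press.
  Lowering the threshold never un-rejects a trial (tested property).
- **Baseline.** Per trial and channel, the mean over [−100, 0) ms is
  subtracted.
- Pipeline order: filter → epoch → reject → baseline. The offline path for
  a recording that was already high-passed at acquisition applies only the
  40-Hz low-pass; both filters are individually callable.

## 4. Statistical conventions

- All t-tests are two-sided; p-values from Student's t. Zero-spread
  degenerate cases: t = 0, p = 1 when the mean equals the null value,
  otherwise a signed infinite statistic with p = 0.
- **Window labelling and snapping.** Sliding windows are labelled by their
  nominal midpoints (multiples of the 2-ms step; the 90–110 ms window is
  labelled 100 ms). At 512 Hz the 2-ms grid is not sample-aligned; window
  edges snap to the nearest sample while the nominal midpoint is reported.
  Measurement windows are half-open [start, end), so adjacent windows
  (50–70, 70–90, 90–110) tile exactly.
- **Peak latency** is the signed extremum (caller-specified polarity —
  an absolute-value criterion is deliberately not offered) at
  nearest-sample resolution; ties break to the earliest latency, so a flat
  window returns its start (with a warning).
- **Pooling** across condition labels is trial-weighted (each surviving
  trial counts once); an unweighted mean of sub-condition averages can be
  had by averaging the sub-conditions separately and grand-averaging.
- **Onset-scan range.** The onset detector's default analysis range is
  50–110 ms: from the earliest cortical response onset to just past the
  latest early-effect peak. The consecutive-window rule does not control
  the familywise error at α: 20-ms windows at 2-ms steps overlap 90%, so
  any noise excursion that reaches significance tends to stay significant
  for well over 5 consecutive windows, and the null firing rate grows
  roughly linearly with the number of window-length spans scanned
  (measured: ~0.25–0.30 for a 0–150 ms scan under every noise composition
  tried, falling to ~0.06–0.08 for 50–110 ms). Restricting the scan to the
  physiologically meaningful early period is therefore both the
  scientifically honest choice and the one that keeps the detector's null
  behavior near its nominal level. No further multiple-comparison
  correction is applied beyond the k-consecutive criterion.
- **Jackknife site selection** is fixed and caller-specified (e.g. the
  contrast effect measured at its maximal site, the C1 at the midline
  site). Selecting the site inside the leave-one-out loop would be an
  alternative; it is not implemented because it changes the estimand.
- The behavioral ANOVA across cohorts is between-subjects (one-way); no
  sphericity correction is involved.

## 5. Behavior scoring

A target is hit if a response falls in the half-open window
(200, 1200] ms after it (the printed convention "from 200 ms to 1200 ms"
leaves endpoint handling open; half-open is recorded here as the package's
choice). Each response credits at most one target — the nearest preceding
eligible one, and only if not already credited; multiple presses in one
window count once, with RT taken from the first crediting press. The
adaptive luminance rule treats the 80–90% band edges as strict
inequalities: hit rate > 0.90 dims the target's green value by 10,
< 0.80 brightens by 10, equality leaves it unchanged; values clip to
[0, 255], making the rule idempotent inside the band.

## 6. File formats

Epochs travel as a JSON sidecar (schema version, montage, sampling rate,
time axis, labels, rejection mask and reasons, optional per-trial onset
times) plus a raw little-endian float32 binary in (trial, channel, sample)
order — bit-exact and language-neutral. In-memory float64 data is downcast
on write; a container read back and rewritten is byte-identical. Event
tables are TSV with columns `time_s`, `type`, `label`. EDF import is a
thin optional wrapper (requires `mne`); it converts to microvolts and
adopts channel names as the montage.

## 7. Replicate-study problem sizes

The recovery study runs 100 replicates of a 24-subject, 576-trial,
single-site cohort (plus 200 null replicates) through the fast path;
the end-to-end trial-level pipeline is exercised at reduced cohort sizes
(4–12 subjects, 8–192 trials) chosen so the full suite stays interactive.
The cohort and trial counts of the replicate study are the study-design
values; only the montage is reduced to the measurement site, which the
single-site statistics never notice.

## 8. Known limitations

- The independent-design jackknife pools per-group leave-one-out variances
  in the standard two-group form; alternative poolings exist and the
  choice matters only at small, unequal n.
- `detect_onset` reports the *statistical* onset, which trails the true
  departure from zero at realistic SNR; treat recovered onsets as upper
  bounds on the physiological onset.
- The epochs container stores float32; data with meaningful sub-float32
  structure (none in this domain) would lose precision.
- Site selection for peak measurements is static; no scalp interpolation
  or fractional-area/fractional-peak latency criteria are provided.
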