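# Methods

This note documents the models, defaults and numerical choices behind
`archepsy`, and what the synthetic cohort does and does not establish.

## Study design being modelled

Each of *n* subjects (default 25) views eight ~5-minute film clips: four
archetype conditions (anima, animus, hero, shadow) and four explicit
emotions spanning the arousal × valence quadrants. Every clip is
preceded by a 40-s paced-breathing baseline at 14 breaths/min. Four
autonomic channels are recorded — ECG (512 Hz), skin conductance
(256 Hz), respiration and skin temperature — and after each clip the
subject reports arousal, valence and dominance on the 1–9 SAM scale.
The analysis asks how well the stimulus class can be decoded from the
physiology versus from the introspective report.

## Synthetic cohort

The generator models only the properties the downstream features
measure.

* **ECG.** Beat times follow an RR process
  `RR = (60/HR) · (1 + s·(0.03 sin 2π·0.1t + 0.02 sin 2π·0.25t + ε))`,
  with `ε ~ N(0, 0.01)` white beat-to-beat jitter and `s` the
  per-class/per-subject HRV scale. The 0.1 Hz and 0.25 Hz terms give
  controllable LF and HF spectral power. Each beat is rendered as a
  unit-amplitude Gaussian R-wave (σ = 12 ms) on 0.02-amplitude white
  noise. No P/T waves, ectopy or movement artifacts are modelled; beat
  *timing*, not morphology, drives every extracted feature.
* **Skin conductance.** Tonic level + linear drift (µS/min) + a slow
  0.01 Hz sinusoid; phasic events at Poisson onsets (rate in
  events/min) with bi-exponential kinetics (1 s rise, 3 s decay,
  log-normal amplitudes around 0.4 µS) — standard electrodermal shape
  assumptions.
* **Respiration** is a sinusoid at the breathing rate plus 1 Hz
  band-limited noise; **temperature** is level + slope·t plus slow
  low-amplitude noise. Respiration and temperature are generated at
  32 Hz (a convention of this package; the temperature path resamples
  to 64 Hz before filtering, matching how slow channels are commonly
  stored and processed).
* **SAM reports** are per-dimension normal draws rounded and clipped to
  [1, 9]. The per-class means and SDs are the published cohort
  descriptive statistics for all eight classes (e.g. anima arousal
  5.320 ± 1.520).
* **Between-subject variance**: resting heart rate N(70, 7) bpm, tonic
  SCL N(5, 1.5) µS, baseline temperature N(33, 0.4) °C, a breathing-rate
  offset N(0, 1) and a log-normal HRV factor, drawn once per subject.
  Epoch-level noise (heart rate SD 2 bpm, etc.) limits class
  separability.
* **Class effects** perturb heart rate (−0.2…+1.8 bpm), phasic event
  rate, tonic drift, breathing rate, temperature drift and HRV scale
  per class. No per-class parameter table exists for the original
  recordings, so these are package conventions calibrated once so that
  the default cohort yields roughly 50 % four-class leave-one-out
  accuracy at `effect_size = 1` — the above-chance but far-from-ceiling
  regime the real data sits in. They are a calibration aid, not an
  empirical claim. `effect_size` interpolates every effect linearly
  toward the shared resting state, and SAM means toward the neutral
  midpoint 5; at 0 the cohort is exchangeable across classes by
  construction.
* **Randomness** fans out from one root seed through per-subject and
  per-epoch `SeedSequence` substreams, so cohorts are bit-reproducible
  and a subject's data does not depend on cohort size bookkeeping.

Because the generator's class structure is stylised, passing tests show
that the *pipeline* recovers structure that is present and reports
chance when it is absent — they say nothing about how large such effects
are in real recordings, nor do they reproduce the original study's
accuracy tables.

## Signal processing

All filters are 4th-order Butterworth (2nd order where the band is a
single-sided conditioning step) applied forward–backward
(`sosfiltfilt`), so they are zero-phase and never move event times.
Cutoffs: ECG pass-band 0.5–100 Hz with a 49–51 Hz band-stop; SCL 1 Hz
low-pass; SCR = the same low-pass cascaded with a 0.5 Hz high-pass;
respiration 0.1–10 Hz; temperature 10 Hz low-pass after polyphase
resampling to 64 Hz (line-padded to avoid edge bias). Note a cascaded
SCR can never exceed the SCL gain at any single frequency; the two
components differ in *selectivity* (SCR rejects slow content, SCL keeps
it).

Beat detection is Pan–Tompkins-style: 5–20 Hz band-pass, derivative,
squaring, 150-ms moving-window integration, an adaptive amplitude
threshold (median + 25 % of the 99th-percentile excess) with a 250-ms
refractory period, then refinement of each candidate to the local
band-passed maximum. RR intervals outside 200–3000 ms are discarded; no
further ectopic-beat correction is attempted. On the synthetic ECG at
20 dB SNR the detector recovers ≥ 99 % of beats within 10 ms.

Windowed series use contiguous non-overlapping 10-s windows
(`floor(duration/10)` of them; a trailing partial window is dropped).
Heart-rate windows assign each RR interval by its midpoint and use
`60000 / mean(RR ms)`; an empty window is imputed from the nearest
non-empty one and flagged. Respiration rate comes from breath-peak
intervals interpolated to an instantaneous-rate series before window
averaging. Spectral HRV interpolates the tachogram with a cubic spline
at 4 Hz, detrends linearly and integrates a Welch periodogram
(nperseg ≤ 512 samples) over the conventional bands.

## Feature extraction

The canonical vector has 158 named entries: `hr_seg_01..30`, the eight
HRV measures, `scl_seg_01..30`, `scr_seg_01..30`, `resp_seg_01..30`,
`temp_seg_01..30`. SCR segment values are the mean absolute phasic
amplitude per segment (an event detector is deliberately not used).

Baseline referencing subtracts the mean of the windowed series over the
40-s baseline epoch, per subject × class × signal. Min–max scaling then
maps the baseline-subtracted values to [0, 1] using extrema pooled
**within subject and signal type across that subject's eight stimulus
epochs**. Pooling within subject is what serves the normalization's
purpose (removing between-subject offsets while preserving
between-class contrasts within a subject); normalizing each epoch
against only itself would erase level differences between classes, and
pooling across subjects would reintroduce the offsets. A degenerate
scope (max = min) yields zeros with a warning. Epochs shorter than the
canonical 300 s are right-padded by holding the last segment value and
logged.

## Modeling

Columns are standardized before PCA because the vector mixes [0, 1]
segment features with unnormalized HRV powers spanning orders of
magnitude. The default `leakage_mode="strict"` refits standardization
and PCA inside every leave-one-out fold so the held-out row cannot
influence the transform; `"pooled"` fits once on all rows for users who
want the leakier but common variant. PCA is fit on the pooled
eight-class matrix by default (`pca_scope="per_task"` is available).
Classifiers: kNN with k = 20 (archetypes) and 25 (emotions), Gaussian
naive Bayes on the continuous component scores, and LDA with a small
ridge (shrinkage 1e-4, `lsqr` solver) so degenerate covariances — e.g.
identical SAM reports — are handled. SAM classification is LDA on the
raw three dimensions.

## Triplet resampling

All C(n,3) three-subject groups are enumerated in lexicographic order.
Each group has 12 epochs per task (3 subjects × 4 classes); folds for
the 3-fold cross-validation are the subjects themselves, which makes
every fold stratified (one sample per class) and avoids within-subject
leakage. The group-level kNN uses k = 3 — with only 8 training rows per
fold a large k would swamp the vote — and breaks voting ties by the
larger summed inverse distance, then lexicographic class order. The
paired t-test is `t = mean(d)/(sd(d)/√n)` with df = n − 1; comparison
against chance treats 0.25 as a repeated constant. Identical samples
return t = 0, p = 1; constant non-zero differences raise a
degenerate-variance error.

Overlapping triplets share subjects, so the 2300 per-group accuracies
are positively dependent and the t-tests on them are anti-conservative;
the procedure is reproduced as designed, and
`disjoint_partition_t` offers an independent-groups diagnostic
(floor(n/3) disjoint triples, one seeded partition) with honest but few
degrees of freedom.

## Problem sizes and runtime defaults

The default cohort is 25 subjects × 8 classes with 300-s stimulus and
40-s baseline epochs — the full design. A complete study (simulation
through all 9200 group evaluations) takes tens of seconds on one CPU.
The effect-size monotonicity check in the test suite uses 10-subject
cohorts (120 exhaustive triplets each), which the package treats as its
standard desk-scale sensitivity analysis. Persisting raw channel tables
for a full cohort writes ~2.5 GB of CSV; `persist_signals=false` keeps
runs table-only, and in-memory runs (`study_in_memory`) skip disk
entirely.

## Known limitations

* The ECG model has no realistic morphology, artifacts or sensor
  dropout; detector performance on it is an upper bound.
* The respiration-rate estimator is peak-interval based and assumes a
  dominant breathing oscillation; highly irregular breathing would need
  a different estimator.
* Clip lengths are fixed at 300 s; real stimuli of "approximately five
  minutes" vary, which the padding rule only approximates.
* Class-effect magnitudes are conventions; absolute accuracies from the
  synthetic cohort are not estimates of any real-data quantity.
* The exhaustive-triplet t-tests inherit the dependence of overlapping
  resamples (see above); treat their p-values as procedure-faithful,
  not as calibrated type-I error.
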