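# Methods

`tffo` implements a four-stage pipeline for discriminating two EEG
populations — schizophrenia patients and healthy controls — from short,
stimulus-locked, single-electrode segments, together with a synthetic
cohort simulator that provides the statistical structure the pipeline
assumes.  This note records the models, the parameters that matter, the
numerical conventions, and the design choices that were genuinely open.

## The discrimination pipeline

**Preprocessing.**  Each recording is band-pass filtered 0.1–30 Hz with a
4th-order Butterworth applied forward–backward (zero phase, so event-locked
latencies are not shifted; measured stop-band attenuation of a 50 Hz tone
is ≈ 37 dB), then scaled so the total energy Σx² over all channels and
samples equals 1.  Global (rather than per-channel) normalization is the
default because electrode ranking depends on the inter-channel amplitude
topography; `per_channel=True` is available.  The recording keeps a
`scale_to_uv` factor so later stages can reason in physical μV.

Epochs of ⌊1.2·fs⌋ samples (614 at 512 Hz) are cut from −200 ms to
+1000 ms around each predictive-sequence ("P") stimulus.  An event is
excluded from **all** channels when, in fixed precedence order:

1. *other* — the epoch would cross a recording edge;
2. *miss* — no button press 150–1150 ms post-onset;
3. *saccade* — a step-like horizontal-EOG deflection: the maximum
   difference between medians of 100 ms flanks around a sliding split
   point exceeds 40 μV (a simple, reproducible stand-in — the field has no
   single canonical criterion);
4. *amplitude* — any EEG channel exceeds 75 μV anywhere in the epoch,
   evaluated on the filtered signal restored to physical μV (i.e., before
   energy normalization; EOG channels are exempt, since ocular deflections
   are handled separately).

The precedence makes each excluded event carry exactly one logged reason,
which is what the audit tests compare against the simulator's ground
truth.

Ocular artifacts are removed with ICA (FastICA, as many components as EEG
channels, seeded and deterministic): components whose absolute Pearson
correlation with either EOG channel exceeds 0.7 are zeroed and the signal
reconstructed.  If nothing crosses the threshold the signal is returned
bit-identical.  The identification rule is ours; component counts and the
threshold are configurable.

**Time-frequency transform.**  The Stockwell transform (S-transform) is a
time-frequency representation with a Gaussian analysis window whose width
scales as 1/f and with phase referenced to t = 0.  The discrete transform
treats the epoch as one period (circular convolution per voice, the
standard FFT-based convention); voices are spaced fs/N Hz and the f = 0
voice holds the signal mean.  Two kernels are provided:

* `classic` (default) — the unit-area window |f|/√(2π)·exp(−t²f²/2).
  Unit area makes a pure tone's magnitude localize at its own voice,
  which the voice-localization tests require.
* `plain` — the unit-height window exp(−π t² f²).  Its area is 1/f, so
  voice amplitudes grow toward low frequencies; it is kept because
  classification is invariant to a global amplitude factor but not to
  window width, and the direct-summation oracle tests are run against it.

By default the transform is applied to the analytic representation of the
frame (negative frequencies zeroed, positive doubled).  With the two-sided
spectrum the ± spectral images of a real tone interfere near Nyquist and
voices within ~3 of N/2 mis-localize; the analytic convention removes the
interference while leaving magnitudes elsewhere essentially unchanged.
`analytic=False` restores the raw convention, and the oracle-equivalence
test covers both.

**Features.**  For a grid coordinate (electrode, window, band, n_events),
the first `n_events` surviving epochs in trial order are averaged
(`average-then-transform`, the default; `transform-then-average` is kept
for sensitivity analysis), transformed, and the magnitude map restricted
to the window × band rectangle and flattened (time-major).  The search
grid pairs each time-window width with its step (100 ms ↔ 25 ms,
500 ms ↔ 50 ms over 0–1000 ms) and each band width with its step
(5 Hz ↔ 1 Hz, 10 Hz ↔ 2 Hz up to 30 Hz) — deliberately redundant,
heavily overlapping windows.

**Classification.**  KNN with the Euclidean metric, subject-wise
leave-one-out: all vectors of the held-out subject are withheld, its
prediction is the majority label of the K nearest training vectors, and an
even-K tied vote is decided by the single closest neighbor.  K is bounded
by ⌊n_train/2⌋.  Healthy is the negative class for specificity.  Each
fold also yields a normalized neighbor margin
(d_opposite − d_own)/(d_opposite + d_own); the cell-level mean margin is a
continuous separation measure used to rank cells whose accuracy has
saturated at 1 (see below).  Significance is a label-permutation test with
plus-one correction, p = (1 + #{perm ≥ observed})/(n_perm + 1); the
method for the original study's p-values is not specified, so the
permutation test is this package's convention.

Two statistical facts matter when interpreting nulls and are encoded in
the tests rather than glossed as "chance = 1/2":

* Subject-wise LOO chance is (n_own − 1)/(n − 1), strictly below 1/2,
  because the held-out subject's own class is under-represented in its
  training set (11/23 ≈ 0.478 for 12 + 12 subjects).
* The permutation p attains its floor 1/(n_perm + 1) only when no
  permutation can reproduce the observed labelling; with equal class
  sizes the exact complement is always reachable and ties the observed
  accuracy.

**Grid optimization and marginals.**  `run_grid` evaluates every cell of
electrode × window × n_events × K.  Per-subject transforms are cached per
(electrode, n_events), so cost scales with transforms rather than cells.
Cells are independent of evaluation order.  The best cell is the highest
accuracy, with ties broken first by the mean neighbor margin and then
positionally (earliest window, lowest band, fewest events, smallest K).
The margin tie-break exists because at a clearly separable effect dozens
of neighbouring cells reach accuracy 1.0 — the transform's ±1/f time
spread and the burst's few-Hz spectral width leak discriminative energy
into adjacent windows — and a purely positional rule would then report a
leakage cell systematically early and low.  `marginal` reduces the grid
along one dimension (electrode, window, time window, band, event count,
K) to mean and best accuracy, supporting electrode-ranking,
accuracy-vs-events, time-window and band curves.  No nested
cross-validation corrects the optimism of reporting the best cell; this
mirrors the original protocol and is a known limitation.

**Severity.**  Each patient's feature vector is summarized by the
Euclidean distance to the healthy group's mean vector (for healthy
subjects the centroid excludes the subject itself).  The distance is
log-transformed by default — it is strictly positive and right-skewed;
the transform is configurable because the original choice is unnamed.
Hospitalization counts map onto the exponential scale
(1, 2, 3–4, 5–7, 8–15, 16+) → ranks 1–6.  Rank is regressed on transformed
distance with closed-form one-predictor ridge (slope = Sxy/(Sxx + λ)); λ
is chosen by leave-one-out CV over a log grid including 0 when not given.
Both in-sample and LOO R² are reported to expose optimism.  The
severe-half check counts how many of the top-k patients by a clinical
covariate fall in the ⌈n/2⌉ patients with the largest distance
(hypergeometric expectation k·⌈n/2⌉/n under independence).

**Latency baselines.**  PE-Latency reduces each subject to the mean
latency of peak squared amplitude per epoch and splits subjects by
2-means (majority cluster→label mapping, which can only err upward, so
its null accuracy sits slightly above 1/2).  P300-RF-Latency histograms
per-event peak latencies inside a conventional 250–500 ms window (10
fixed bins; the window is configurable since no bounds are canonical) and
feeds the histograms to the same KNN-LOO machinery.

## The synthetic cohort generator

The generator's defaults encode the emulated protocol: 25 subjects per
group, a 64-channel 10-20 montage (plus `EOGv`/`EOGh`) at 512 Hz, blocks
of 78 triangle stimuli of 150 ms at 1 s ISI in which every second triple
is the predictive left-up-right sequence, giving 13 "P" events per block;
responses are lognormal-ish button presses ~400 ms after onset.

Signal model per subject:

* **Background** — per-channel Gaussian noise with power spectrum
  ∝ f^−1.5 (10 μV RMS) plus a 1 μV white floor, mixed with a spatially
  common component (30% of variance for EEG, 10% for EOG) as a cheap
  stand-in for volume conduction.  The 1.5 exponent is mid-range for
  resting EEG (1–2); it also sets how much background power lies in the
  beta band and was fixed once when the study conditions were calibrated.
* **Evoked response** — at every "P" event, each EEG channel receives a
  Gabor burst: carrier at the effect-band center (17.5 Hz by default),
  Gaussian envelope with σ = 40 ms centered in each effect window
  ([200, 300] and [900, 950] ms by default), peak amplitude 20 μV at the
  first trial.  A 40 ms envelope gives a ~4 Hz spectral sd, wide enough
  to stay inside a 100 ms window but narrow enough that the injected
  energy is maximal in the nominal 5 Hz band — the time-frequency
  uncertainty product makes perfect confinement in both a 100 ms window
  and a 5 Hz band impossible, and this is the compromise.  Burst
  amplitude decays as exp(−i/τ) over the P-event index (habituation,
  τ = 3 trials by default: only early trials carry strong responses).
  All trials share a 5 ms latency jitter.
* **Group difference** — confined to the effect channels (`F2`, `FC3` by
  default): patients' bursts are scaled by the amplitude ratio
  `effect_size` and additionally latency-shifted (30 ms at full effect)
  and jittered (10 ms at full effect, in quadrature), with both latency
  modulations proportional to 1 − ratio so that `effect_size = 1` is an
  exact null by construction.  With a severity model attached, each
  patient's ratio interpolates between 1 and `effect_size` according to a
  latent severity s ∈ [0, 1] through a monotone link; hospitalizations
  (1 + Poisson(4s)), SAPS/SANS counts (Binomial(20, s)) and medication
  load are monotone-in-s draws, which is what makes severity recovery
  testable.
* **Artifacts** — drawn independently per epoch: blinks (300 ms
  raised-cosine, 200 μV on EOGv, scaled down frontal→posterior), saccades
  (smoothed 60 μV steps on EOGh), large-amplitude events (120 μV bumps on
  one random EEG channel), and misses (button press deleted).  Every
  contamination is recorded in a ground-truth table attached to the
  recording.

All randomness descends from a single `SeedSequence`; identical
(spec, seed) produces bit-identical float32 signal matrices.

What the generator does **not** emulate: biophysical forward modeling,
realistic eye-movement kinematics, non-stationary background (drowsiness,
alpha blocking), line noise, electrode drift or impedance artifacts, or
any claim about the true clinical effect size — the original recordings
are not deposited, so `effect_size` is a free parameter and passing tests
demonstrate internal consistency of the method, not clinical performance.

## Calibrated study conditions and problem sizes

The packaged verification runs at desk scale, chosen once:

* parameter recovery: 20 cohorts of 25 + 25 subjects on an 8-channel
  montage, effect at [200, 300] ms × [15, 20] Hz on F2/FC3 at
  `effect_size = 0.3`, searched over a reduced overlapping grid (100 ms
  windows sliding by 50 ms; 5 Hz bands sliding by 2.5 Hz; K ∈ {1, 3};
  8 events).  At this operating point the effect cell's LOO accuracy is
  0.98–1.0, comfortably above the 0.9 requirement, and the top cell
  coincides with the injected structure in ≥ 80% of cohorts.
* null calibration: 50 cohorts of 12 + 12 subjects at `effect_size = 1`;
  permutation p-values (199 permutations) tested for uniformity and mean
  accuracy against the LOO chance level 11/23.
* event-count marginal: 5 cohorts of 25 + 25 at a weaker contrast
  (burst 10 μV, `effect_size = 0.4`, τ = 3), where the curve reaches its
  plateau within a few events and stays within 0.1 of its maximum —
  beyond the knee, averaging in habituated (signal-free) trials dilutes
  the per-epoch SNR as τ(1 − e^{−n/τ})/√n, so "flat" is the realistic
  expectation, not continued growth.
* severity recovery: 50 simulated patient sets of n = 25 with
  rank = affine(z), distance = z + ε, recovering the analytic attenuation
  R² = 1/(1 + σ²/var z).

## Numerical conventions and degenerate inputs

* 0-based sample indexing; user-facing times in ms relative to stimulus
  onset; ms→sample conversion rounds half to even; epoch length is
  ⌊1.2·fs⌋.
* Window/band selection on the magnitude map is inclusive of both edges.
* Distance ties in the KNN vote and covariate ties in the severe-half
  check are broken by stable subject order; grid argmax ties as described
  above.  All of it is deterministic.
* Degenerate inputs fail loudly: all-zero recordings cannot be
  normalized, zero-variance predictors cannot be regressed, single-subject
  classes cannot be cross-validated, hospitalization counts below 1 are
  rejected, NaN/Inf frames are rejected by the transform.

## Known limitations

* EDF/BDF files can be read (through `mne`) but not written; the fixture
  format (float32 matrix + JSON sidecar + TSV events) is the supported
  interchange and round-trips bit-exactly.
* The best-cell accuracy is optimistically biased (no outer validation
  split); marginals inherit the same selection effects.
* The saccade detector and the ICA component-selection rule are
  reasonable stand-ins for unspecified steps, not validated artifact
  classifiers.
* Subject-wise LOO with small cohorts has coarse accuracy granularity
  (1/n); properties are therefore asserted on seed-averaged quantities.
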