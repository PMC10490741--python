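# Methods

`mibci` implements a multiclass motor-imagery (MI) EEG classification
pipeline in which channel-local, translation-invariant spectral features
from a wavelet scattering network are fused with inter-channel
functional-connectivity features, ranked by a multiclass Fisher score,
and classified by a one-versus-the-rest (OVR) RBF-kernel SVM under two
session-transfer protocols. This note records the model, the defaults
and the numerical choices, and what the synthetic experiments do and do
not establish.

## Paradigm and preprocessing

The target recording format is the standard four-class cue-based MI
benchmark: 22 EEG channels at 250 Hz, two sessions per subject recorded
on different days, 288 trials per session (72 per class: left hand,
right hand, feet, tongue), 7.5 s per trial with the cue at 2 s. Analysis
uses the 2.5–5 s window where event-related
desynchronization/synchronization (ERD/ERS) is most prominent — 625
samples under the half-open `[start*fs, end*fs)` convention used for
every window in the package.

Preprocessing per session:

1. zero-phase Butterworth band-pass, 8–30 Hz (covering μ and β), applied
   forward and backward so the effective magnitude response is the
   squared single-pass response. The per-pass order is not dictated by
   the problem; the default is 4, exposed in `PipelineConfig`. Edge
   handling is odd-reflection padding of length 3× the filter state
   length, the standard forward–backward recipe;
2. baseline correction: subtraction of each channel's mean over the
   fixation period. The baseline window is a free choice; the default is
   (0, 2) s;
3. common average reference (CAR);
4. epoch extraction and exclusion of artifact-flagged trials.

Band-pass and CAR are both linear and commute to numerical tolerance
(tested). A 50 Hz notch is available for raw-recording adapters but off
by default, since the benchmark recordings ship notch-filtered.

## Connectivity features (BCFs)

Per epoch and channel the analytic signal `z(t) = x(t) + i·H[x](t)` is
computed with the frequency-domain discrete Hilbert transform (no
padding; edge effects over a few cycles at each end of the 625-sample
epoch are accepted). Instantaneous phase is the four-quadrant
`arctan2(H[x], x)`: a two-quadrant ratio form would discard the sign of
`x(t)` and break phase continuity. Three pairwise metrics:

* **PLI** `= |mean(sign(Δφ))|`, with `Δφ` wrapped to (−π, π] before the
  sign and `sign(0) = 0`, so zero-lag (volume-conduction-like) coupling
  scores 0;
* **phase correlation (PC)**: Pearson correlation of the two wrapped
  phase series. Wrapped phases are the default because the statistic is
  defined directly on φ; an `unwrap` switch exists because unwrapping
  genuinely changes the statistic. Population (divide-by-N) moments are
  used consistently in covariance and variances — the ratio is invariant
  to the convention, which a test enforces;
* **Pearson** correlation of the band-passed signals (an
  instantaneous-amplitude mode is a possible alternative; signals are
  the default).

All channel pairs of the full montage form a symmetric adjacency matrix
per epoch; its strict upper triangle in row-major order is the BCF
vector, `nc(nc−1)/2 = 231` values for 22 channels. For visualization,
per-epoch matrices are Z-scored over their off-diagonal entries and
averaged within class; class contrasts are elementwise differences of
those averages.

## Scattering features (TIFs)

The scattering network is a fixed-filter convolutional cascade: analytic
Morlet wavelets (Gaussian bumps in frequency with an exact zero-mean
correction), complex modulus, and a Gaussian low-pass `φ` of invariance
scale `T` (default 2 s). Coefficients are order 0 (`x*φ`), order 1
(`|x*ψ_λ1|*φ`), and order 2 (`||x*ψ_λ1|*ψ_λ2|*φ` for `ξ2 < ξ1`). The
first-order bank has Q1 = 8 wavelets per octave (resolves μ vs β), the
second Q2 = 1 (dyadic, amplitude-modulation structure), tiling
`[fs·2^(−J), 0.4·fs]` with `J = round(log2(T·fs))` (= 9 at the
defaults). Convolutions run on a reflection-padded copy of the epoch
because circular wrap-around is material at this epoch length.

Two numerical choices deserve emphasis:

* **Normalization.** The wavelet banks are rescaled so the
  Littlewood–Paley sum `|φ̂|² + Σ|ψ̂_k|²` is ≤ 1 everywhere while `φ`
  keeps unit DC gain. This makes every stage of the cascade
  non-expansive (`‖S(x)−S(y)‖ ≤ ‖x−y‖`, fuzz-tested), bounds the output
  energy by the input energy, and makes the order-0 response to a
  constant equal that constant.
* **Output resolution.** Each path's low-passed output is sampled at
  half-overlapping frames of stride `T/2` — two frames per 2.5 s epoch
  at `T` = 2 s, ten at `T` = 0.5 s — rather than collapsed to one global
  time average. A global mean is almost exactly shift-invariant at
  *every* scale, which makes the invariance scale a dead parameter (and,
  empirically, slightly worsens invariance at larger `T` through the
  boundary leakage of the added low-frequency wavelets). With frame
  sampling and a low-pass whose time standard deviation equals `T`, a
  100 ms shift of content away from the epoch edges changes the feature
  vector by about 14%/8%/4% of its norm at `T` = 0.5/1/2 s — invariance
  genuinely improves with the scale, as it should.

TIFs are extracted on a channel subset. The default is the 11-channel
midline-centred set {FC1, FCz, FC2, C3, C1, Cz, C2, C4, CP1, CPz, CP2}:
the natural "fronto-central + central + centro-parietal rows" reading of
a half-montage subset contains 17 electrodes of the standard 22-channel
layout, not 11, so a choice had to be made; the midline-centred 11 keeps
the C3/Cz/C4 motor sites and their immediate neighbours and is
config-overridable. Coefficients are used raw (no logarithm) by default
so the non-expansive property stays testable; a log switch exists.

## Fusion, selection, classification

Fusion is serial concatenation (an n-dimensional TIF vector and an
m-dimensional BCF vector give n+m features), with provenance tags so the
fused matrix can be sliced back into its sources. The multiclass Fisher
score per feature is the count-weighted between-class scatter over the
count-weighted within-class (population) variance. If the pooled
within-class variance is zero the score is 0 for a constant feature and
+∞ for a zero-variance separating feature — such a feature is maximally
discriminative and ranks first. Ties in selection break by ascending
feature index, making selection deterministic.

The classifier is an OVR ensemble of RBF SVMs decided by argmax of the
per-class decision values. Features are z-scored with training-set
statistics (RBF kernels are scale-sensitive; switchable). `C`, `γ` and
the number of selected features `S` are chosen jointly by grid search
over the mean accuracy of a 10-fold stratified cross-validation on the
training set, with Fisher scoring, selection and standardization refit
inside every fold — no test (or validation-fold) information reaches the
selector. Fold assignment uses a fixed documented seed. The number of
selected features is not a given of the problem; the default grid is
{50, 100, 200, 400}. The winning triple is refit on the full training
set and the reported "validation accuracy" is the winning mean CV
accuracy. Whether the grid search should wrap the CV (as here) or nest
inside it is genuinely ambiguous; the wrapping reading is implemented
and documented.

Two transfer protocols:

* **SST** (session-to-session): train on session 1, test on session 2;
* **CST** (calibration-session): per class, the chronologically first
  `floor(0.40·n)` epochs of session 2 join the training set; the rest
  are the test set. "First" is recording order, and flooring keeps the
  calibration fraction at or below its nominal value.

Metrics: accuracy (trace of the confusion matrix over its total, in
percent), Cohen's κ `(p_o − p_e)/(1 − p_e)` with `p_e` from the row and
column marginals, and macro-averaged one-vs-rest precision and recall
(with balanced classes, micro-averaging would collapse onto accuracy and
say nothing new; a never-predicted class contributes 0 to its average).
Cross-subject aggregation reports the mean and the sample (n−1) SD.

Paired comparisons between feature cases use an exact two-sided Wilcoxon
signed-rank test: zero differences dropped, midranks for ties, and the
null distribution of the positive-rank sum enumerated exactly (a dynamic
program over doubled ranks; verified against brute-force enumeration for
all n ≤ 12). At n = 9 subjects the exact test is the appropriate choice;
the two published case comparisons reproduce from the printed
per-subject accuracy columns as p = 0.0039 (SST) and p = 0.0156 (CST).

## Synthetic data: what it emulates and what it does not

No generative model of the benchmark EEG exists, so the generator's
signatures are explicit artifice, designed so each feature family has a
ground truth it alone should recover:

* background: white noise plus AR(1) (a = 0.95) pink-ish noise, and μ
  (10 Hz, amplitude 1.0) and β (20 Hz, amplitude 0.8) rhythms with
  slowly diffusing phase on every channel — an EEG-like 1/f-plus-rhythms
  spectrum without a head model;
* **ERD plant**: on designated channels the rhythm inside `erd_band` is
  scaled by `1 − erd_depth` during the imagery window (raised-cosine
  ramps, 0.2 s). Detectable by channel-local spectral features only;
* **coupling plant**: every channel always carries a narrow-band carrier
  (amplitude 6, i.e. dominant over the in-band background; 10 Hz with
  ±1 Hz per-trial jitter and phase diffusion), gated to the imagery
  window. For a coupled pair the carrier is
  `sqrt(1−s²)·independent + s·shared` with the shared process lagged by
  the configured phase on the second channel. The mix is
  energy-preserving and the shared process has the same jitter and
  diffusion statistics as the independent ones, so channel-local
  statistics are identical across classes and the plant is visible
  *only* in the cross-channel phase relation. At `s` = 1 the planted
  pair's mean PLI exceeds 0.9 while unplanted pairs sit near 0.25.

Artifact trials are flagged (at rate 0.05 by default), not corrupted:
the pipeline's contract is to exclude them, so corruption would add
nothing the tests could see. One integer seed drives every draw of a
session; generation is bit-reproducible.

The recovery experiments run a reduced study — 8 channels, 20 trials
per class, a Q1 = 2 bank on a 4-channel subset, a small hyperparameter
grid — sized so the full seeded suites complete in minutes. Across 20
seeded replicates: with class structure planted only in coupling, the
fused pipeline beats the channel-features-only pipeline in ≥ 18/20 runs
(typically ~80% vs ~28% test accuracy); with identical signatures the
end-to-end accuracy stays within exact-binomial 99% bounds of 25%
chance; a single planted pair lands in the Fisher top-10 of the fused
ranking in ≥ 95% of runs; and with both plants present, fusion is at
least as accurate on average as the better single source.

These experiments validate the *machinery* — that each feature family
recovers exactly the structure it is designed for, that fusion combines
them without leakage, and that nothing separates classes when nothing
was planted. They do not establish performance on real EEG:
the generator has no volume conduction (beyond what CAR induces), no
non-stationarity across sessions, no inter-subject variability, and its
phase coupling is far cleaner than cortical coupling. Published-table
statistics (the Wilcoxon comparisons, cross-subject means) are
recomputed from the printed per-subject values; reproducing those values
from raw recordings requires the external competition dataset, for which
an optional GDF adapter is provided but deliberately untested here.

## Known limitations

* The scattering implementation is the package's own Morlet cascade;
  an adapter seam (`ScatteringConfig` + the `FilterBank` interface)
  allows substituting another implementation, but the built-in cascade
  is the reference and the test target.
* PLI on short (625-sample) epochs is biased upward for independent
  narrow-band signals whose phase difference drifts slowly; the
  generator's carriers diffuse fast enough that unplanted pairs average
  ~0.25, but users analysing real narrow-band data should expect the
  same finite-sample bias.
* CST assumes session-2 epochs arrive in recording order; shuffled
  inputs would silently change "first 40%".
* The exact Wilcoxon implementation enumerates up to n = 25 pairs;
  larger cohorts need the normal approximation, which is out of scope.
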