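# Methods

This note documents the models implemented in `fosdecode`, the defaults
and why they were chosen, and what the synthetic-data experiments do and
do not establish.

## Stimulus geometry and labeling

The wedge-center angle is measured on the screen with 0° at the top
(vertical meridian), increasing clockwise from the subject's viewpoint;
a counterclockwise wedge rotation therefore decreases the angle at
360°/48 s. This convention makes the quadrant arcs — top [−45°, 45°),
right [45°, 135°), bottom [135°, 225°), left [225°, 315°) — agree with
ordinary screen orientation. Arcs are half-open so the four labels
partition the circle; a boundary angle belongs to the arc it opens.
Both the convention and the starting angle (default 0°: wedge starts at
the top) are configurable.

Trials are defined on the continuous time axis: each *quadrant pass*
(maximal interval with a constant label) is tiled from its onset with
400 ms trials. With the default start angle the wedge begins mid-arc, so
the first and last top passes are 6 s halves; every quadrant still
receives exactly 30 trials per revolution, giving the reference
accounting 41 subjects × 8 revolutions × 30 trials × 2 quadrants =
19,680 rows for a binary contrast. 400 ms is 15.625 samples at
39.0625 Hz; trials are snapped to samples only when the 20-sample
analysis window is extracted, so no rounding drift accumulates.

Each trial's feature window is the 20-sample (512 ms) segment centered
on the boundary between the trial and its within-pass neighbor
(successor; the last trial of a pass reuses its predecessor). This
covers the concatenated responses of two 400 ms trials — the
motivation for the 512 ms choice, which maximizes the overlap between
the wavelet cone of influence and the data — while keeping one row per
trial. Windows of neighboring trials overlap by ~112 ms; no window
extends into a differently-labeled pass beyond the one-sample snap
margin.

## Montage and quadrant gains

Optode coordinates are not published for this kind of recording, so the
montage is synthetic: 16 source fibers (each carrying 690 nm and 830 nm
lasers) and 16 detectors on interleaved occipital grids with ±1.5 mm
seeded jitter; all source–detector pairs with separations in
[20, 70] mm are eligible and a seeded subset of exactly 128 pairs per
wavelength is retained. Channel sensitivity to each visual-field
quadrant is a parametric proxy for a photon-transport sensitivity map:
a Gaussian falloff (σ = 35 mm) of the channel midpoint around four
region centroids, with top/bottom contrast along the vertical axis and
a mirrored left/right contrast along the horizontal axis (retinotopic
contralaterality). Physical photon-diffusion modeling is a non-goal.

## Preprocessing

* **High-pass**: windowed-sinc (Hamming) linear-phase FIR, 2 Hz cutoff,
  order 128 targeting a ~1 Hz transition band at 39.0625 Hz, applied
  forward–backward (zero phase, squared amplitude response). The taps
  are mean-corrected so the DC response is exactly zero, and the tiny
  residual mean that reflect-padding leaks in at block edges is
  removed; passband gain at 5 Hz is within 0.2% of unity with zero
  measured group delay, and 0.1 Hz content is attenuated by >140 dB.
* **Optical density**: `log10(DC / DC_block_mean)` with the *unfiltered*
  per-channel block mean, then filtered. Log base 10 follows the
  optical-density convention (the defining equation does not name a
  base). Filtering the log-ratio equals filtering after conversion
  because the conversion is a samplewise affine map in log space given
  the fixed block mean; the alternative order differs only in the
  removed zero-frequency term. The printed sign is kept (positive =
  intensity increase).
* **Time of flight**: phase filtered in degrees, then scaled by
  `1 / (360 · f_mod)`; phase wraps are assumed already unwrapped by the
  instrument.

## Wavelet coherence features

The analytic Morlet wavelet (ω₀ = 6) is evaluated in the frequency
domain on a zero-padded FFT grid. Twelve pseudo-frequencies are
log-spaced over [2, 19] Hz — from the high-pass cutoff to just below
Nyquist. Coherence uses the standard smoothed-cross-spectrum
construction with scale-normalized spectra; smoothing is a per-scale
time boxcar of about one scale length (minimum 3 samples) and a 3-point
boxcar across scales — the minimal smoothing viable on 20 samples
(without smoothing, coherence is identically 1). The reported feature is
the coherency *magnitude* in [0, 1] (a squared-magnitude switch is
provided), averaged over points inside the cone of influence
(e-folding time √2·s from either window edge); a switch admits all
points. On a 20-sample window only scales above ≈5.5 Hz have in-COI
points, so coarser scales contribute nothing to the average — an
intrinsic property of the short-window design, and the reason the
generator's event-locked content (10 Hz reversal rate) lies safely
inside the usable band. The all-channel reference includes the channel
itself, and is recomputed per window.

## Classifier

Features are z-scored per column (population SD); statistics are fitted
on the training folds only and applied to the held-out fold — a
leakage guard; a `normalization="global"` flag restores whole-matrix
z-scoring for comparison. Zero-variance columns map to zeros with a
logged warning.

The SVM is an RBF-kernel classifier with γ = 0.5 under the
dimension-free convention `k(u, v) = exp(-γ·||u − v||² / P)` with P the
number of features. The rationale: between z-scored rows the squared
distance concentrates near 2P, so this convention gives a meaningful
kernel (exponent ≈ −2γ) at any feature count, which is what makes
γ = 0.5 "a standard value for z-scored inputs". The literal
`exp(-γ·||u − v||²)` is available as `gamma_convention="raw"`, and a
test documents its failure mode: at P = 128 the kernel matrix
degenerates to the identity (off-diagonals ~e^-128) and the classifier
collapses to a single class regardless of separability. The
regularization constant C (default 1.0) is config-exposed; no inner
hyperparameter loop is run by default, γ being fixed.

Folds are built by seeding a shuffle of the subject list and dealing
subjects round-robin into 5 folds, so fold sizes differ by at most one
subject and every subject's rows stay together. The default decision
threshold is 0 on the SVM decision score; a Youden-optimal threshold
estimated on the training folds is available.

## Evaluation

Confusion matrix, sensitivity, specificity and accuracy follow the
standard binary definitions with class 1 positive. ROC is a threshold
sweep with trapezoid AUC; a test pins it to the rank (Mann–Whitney)
statistic to 1e-12, ties handled by midranks. Significance uses label
shuffling: the p-value is `(1 + #{null ≥ observed}) / (1 + n_perm)`
(add-one, never exactly 0), with the shuffled-label AUC computed
through the rank identity so 10⁴–10⁶ draws are affordable; the default
is 10,000, configurable up to the million-draw scale. Accuracy
significance uses the same scheme (a binomial test is a near-equivalent
alternative for balanced designs).

ITR is the Wolpaw formula
`B = log2 N + P log2 P + (1−P) log2((1−P)/(N−1))` scaled by
`60 / 0.512` selections per minute. Published ITR tables for this
paradigm are systematically above the plain Wolpaw value at the printed
accuracies (62.95% gives 5.74 bpm, not 5.92), so printed ITRs are
treated as non-normative; this package always reports plain Wolpaw.
Below-chance accuracy clips to 0 bpm with a warning.

## Synthetic data generator

The generator defines the study conditions for all end-to-end tests.
Per subject and channel, log-intensity is the sum of

| component | default | rationale |
| --- | --- | --- |
| white noise | SD 3e-4 | sets single-trial amplitude SNR ≈ 0.3 at the default effect (the low-SNR regime characteristic of fast optical signals) |
| drifts | 3 sinusoids, 0.01–0.3 Hz, amplitude ~2e-3 | slow physiological/instrumental wander, an order above the effect, removed by the 2 Hz high-pass |
| cardiac | ~1.2 Hz, amplitude 5e-4, 5% frequency jitter | pulse artifact below the cutoff |
| effect | 1e-4 per event | fast evoked response; order of 0.01% intensity change |

DC is `baseline · exp(x)` so the optical-density conversion linearizes
the planted components exactly; phase is the analogous additive model in
degrees (effect 1e-2°, noise 3e-2°). Every checkerboard reversal
(2 × 5 Hz) while a quadrant is stimulated adds a ~100 ms raised-cosine
biphasic template at 80 ms latency, shared across channels and weighted
by the channel's gain for that quadrant — so the decodable signal is
inter-channel synchronization, the quantity the coherence feature
measures, not raw amplitude. 830 nm channels carry a 1.5× effect
(longer NIR wavelengths are more sensitive to fast signals); per-subject
gain varies with SD 0.2. Everything is reproducible from
`(seed, subject_index)`.

True per-trial effect sizes for this paradigm are not quantified
anywhere; the defaults above are plausibility choices, not physiology.
What the synthetic experiments establish is *methodological*: the
pipeline recovers a planted synchronization effect (monotonically in
amplitude, with valid permutation inference at zero effect) and does not
hallucinate one. They do not establish that real recordings decode at
any particular accuracy — real data add optode-placement variability,
motion, model-mismatched physiology and non-Gaussian noise that the
generator deliberately omits.

## Problem sizes

The test suite and the acceptance script run cohorts of 2–6 subjects
and 1–2 revolutions (up to 720 trials × 128 channels per run) with
10,000-draw permutation nulls — sizes chosen so a full verification pass
completes in a few minutes on a single core while leaving every
statistical check well-powered. The full reference geometry (41 × 8) is
exercised analytically through the design-accounting functions.

## Known limitations

* The montage, quadrant gains and response template are parametric
  stand-ins; none is validated against photon-transport modeling.
* Coherence smoothing on 20 samples is necessarily crude; features have
  a high noise floor (~0.68 between independent noise signals) and the
  discriminative information is the *pattern* across channels.
* AC signals are carried through I/O but never analyzed.
* No motion-artifact correction or short-channel physiological
  regression is provided.
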