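# Methods

## Decoding model

Each fMRI volume acquired during the movie is one stimulus class, so a run
of T = 150 volumes defines C = T classes with exactly one observation per
class per run.  All classifiers are template matchers: a test volume y⃗ is
assigned the class of its nearest template under a distance D.

* **Nearest-neighbor (NN)** uses each single training run in turn as a
  template set; the global prediction is the argmin over all
  (run, class) pairs, and the per-template-run pairwise accuracies are
  also reported (`PredictionResult.per_run_predicted`), since cross-run
  agreement varies systematically with scan-to-scan differences.
* **Nearest-mean (NM)** averages the R−1 training runs into class
  centroids μ⃗_c, reducing template noise by √(R−1).

Distances: correlation in the plain cosine form 1 − y⃗ᵀx⃗/(‖y⃗‖‖x⃗‖) — no
extra centering beyond preprocessing, which already removes voxel means —
squared Euclidean, variance-normalized squared Euclidean (GNB: diagonal
within-class covariance), and Mahalanobis (LDA: full pooled within-class
covariance).
All Euclid-family distances use the **squared** form: argmin is invariant
under the monotone square root, so one convention serves all classifiers.

The pooled covariance Σ is estimated from training residuals (score minus
its class centroid), pooled over classes and runs, with the
maximum-likelihood divisor N rather than N − C: with C = 150 classes and
≤ 7 training runs the per-class correction is both large and irrelevant,
since a global rescaling of Σ cannot change any argmin.  A relative ridge
`1e-8 · trace(Σ)/K` keeps Σ positive-definite; inversion is by Cholesky
factorization and failure raises rather than silently pseudo-inverting.

### PCA regularization

Σ is rank-deficient in voxel space (residual degrees of freedom
C·(R_train − 1) ≪ V), so Mahalanobis classification requires dimensionality
reduction.  Spatial PCA is fitted to the column-centered run-averaged
training templates; training and test data are projected into that basis
without variance normalization of the scores (signal-strong components keep
their scale — that is exactly what the covariance weighting then acts on).
The default comparison uses 64 PCs.  When a swept fROI is smaller than the
requested dimensionality, `fit` clips K to min(C−1, |fROI|), so 64-PC
classifiers remain defined down to 16-voxel fROIs.  Component signs are
fixed (largest-magnitude loading positive) for bit-reproducibility.

## Feature selection

Per voxel, a fixed-effects one-way ANOVA over C groups with the runs as
replicates: F = MS_between/MS_within with df = (C−1, C(R−1)).  A
within-run-reproducible voxel (MS_within numerically zero, MS_between > 0)
gets F = +∞ and sorts above all finite values; flat voxels get F = 0.  Ties
break by ascending voxel index.  Rankings are computed inside each
cross-validation fold from training runs only; the evaluation layer exposes
a `fold_hook` so tests assert structurally that the held-out run never
enters feature selection.  An optional boolean candidate mask restricts the
ranking (the anatomical-restriction use case); none is applied by default
on synthetic grids.

## Cross-validation and controls

Leave-one-run-out: every model ingredient is refitted on the R−1 training
runs.  Confusion matrices accumulate integer counts over folds (rows =
true); `mean accuracy = trace/sum` exactly.  The misclassification lag
histogram collapses the confusion matrix onto predicted-minus-true offsets;
over-representation of |lag| = 1 errors is judged against a null in which
each error falls uniformly on the C−1 wrong classes.  The chance-level
control permutes each run's labels independently (run structure preserved,
fresh permutation per run per repetition, one seeded stream) and repeats
the full cross-validation; its mean accuracy must sit at ~1/C.

## Synthetic data generator

The generator emulates a repeated-viewing movie study: R = 8 runs × T = 150
volumes at TR = 2 s on a 24×24×12 voxel grid (V = 6912) by default.

Signal: K latent components, each a set of 1–3 signed Gaussian blobs on the
grid.  The `frac_active_voxels` share of voxels with the strongest loadings
forms the active mask; each active voxel then keeps only its strongest
component (winner-take-all), giving components disjoint supports — i.e.
exactly orthogonal spatial maps, the idealization of distinct functional
regions.  Component amplitudes follow a power-law spectrum k^(−amp_decay)
(default 0.5), so the latent variance spectrum decays as empirical PC
spectra do and the eigenbasis is identifiable.  Component time courses are
Bernoulli(0.3)-per-TR event trains convolved with a two-gamma HRF (peak 6 s,
undershoot 16 s, ratio 1/6, dispersion 0.9 s; FWHM ≈ 5.4 s), z-scored, and
then ZCA-whitened across components: convolved random trains are mutually
correlated up to ~0.3 over only 150 samples, which would make the latent
basis unidentifiable for PCA even without noise (measured noiseless
recovery as low as |cos| ≈ 0.7; exact after whitening).  Whitening keeps
the trains HRF-smooth, so adjacent-volume confusability — the ±1 TR error
mode — is preserved (lag-1 autocorrelation ≈ 0.77).

Signal amplitude is set by `snr`, the mean temporal SD of the signal over
active voxels in units of the white-noise SD (1).

Corruption, per run: multiplicative signal gain (SD `run_gain_sd` = 0.1),
additive per-voxel offsets (SD `run_offset_sd` = 0.5), polynomial drift
a·t + b·t² with t ∈ [−1, 1] and coefficients ~ N(0, `drift_amp`² = 1) —
exactly the nuisance form preprocessing removes — plus i.i.d. white noise.
Optionally, `n_noise_components` spatially smooth pure-noise maps with
white time courses (amplitude `noise_component_scale`, relative to the
strongest signal loading) model high-variance stimulus-unrelated sources —
arousal- and vessel-like patterns.  These create anisotropic within-class
covariance, which is what distinguishes the covariance-weighted classifiers
from plain nearest-mean; they are off in the default configuration and on
in the classifier-comparison fixture.  All randomness comes from one seeded
generator in a documented order (maps, trains, noise maps, then per run:
gain, offset, drift, structured noise, white noise), so identical
config+seed is bit-identical, and changing `snr` alone rescales the signal
without changing any noise draw.

What the generator does **not** model: physiological (cardiac/respiratory)
cycles, subject motion, scanner spikes, multi-subject structure, spatial
autocorrelation of the white noise, and temporally autocorrelated noise
(temporal structure enters only through HRF-convolved signal).  Passing
tests therefore demonstrate correctness and calibration of the analysis
machinery under its own assumptions, not performance on real scanner data.

### Fixture conditions for the classifier comparison

The shipped moderate-SNR configuration (`fixture_config`) uses a 16×16×12
grid (V = 3072, so a full cross-validated sweep stays cheap), K = 64
components (the latent rank matches the 64-PC classifiers, so no PC
dimension is a pure selection artifact), 25% active voxels, snr = 0.5,
8 structured noise components at scale 0.8, and the default run-level
corruptions.  Under these conditions the family reproduces the expected
qualitative pattern — accuracy ordering LDA64 ≥ GNB64 ≥ NME ≥ NNE and a
dome-shaped accuracy-vs-fROI curve peaking near the truly active fraction —
in 5/5 tested seeds, with LDA64 in the 0.88–0.99 range.

## Numerical choices

* z-scoring uses the unbiased (n−1) SD; constant columns (SD < 1e−12) are
  zeroed and logged as degenerate instead of dividing by ~0.
* The polynomial time covariate is centered and scaled to [−1, 1] before
  building [1, t, t²], keeping the design well conditioned; residuals are
  computed via QR.
* Rank-deficient nuisance designs raise an error naming the collinear
  columns.
* Ties in any argmin break toward the lowest class index and are counted
  (`n_ties`).
* ANOVA treats MS_within ≤ 1e−12·MS_between as exactly zero (identical
  replicates otherwise round to ~1e−32 and would miss the +∞ convention).
* NIfTI export is float32 (round-trip tolerance ~1e−6 relative); voxel
  flattening is x-fastest, 0-based, and spatial maps are un-flattened by
  the same order.

## Problem sizes used in tests and acceptance

Chance-level control: V = 1728 (12×12×12), R = 4, C = 150, 20 permutations.
ANOVA null calibration: the default V = 6912 grid at snr = 0.  Structure
recovery: 16×16×12 at snr = 5 (accuracy) and snr = 2 (fROI purity);
PCA-map recovery on 12×12×8 with K = 4, snr = 2, amp_decay = 1 (eigenvalue
gaps large enough that best-match |cos| is a recovery measure rather than a
mixing-angle lottery), compared against ground-truth maps expressed in the
z-scored analysis space (a loading m appears as ~ m/√(1+m²) after unit-
variance normalization).  The classifier comparison runs the fixture above
for seeds 0–4 at fROI sizes {16, 128, 768, 3072}.

## Known limitations

* The correlation distance is undefined for zero-norm patterns; constant
  test volumes therefore work with Euclid-family metrics only.
* Covariance estimation warns (not errors) when residual degrees of freedom
  fall below the PC dimension; with very few runs LDA accuracy degrades
  gracefully via the ridge but is no longer well calibrated.
* The per-PC F analysis outside cross-validation (`project_dataset_scores`)
  fits PCA on all runs and is for description, not inference.
* Real-data ingestion expects motion-corrected, spatially aligned NIfTI
  runs; no registration, slice-timing, smoothing, or BIDS handling is
  provided.
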