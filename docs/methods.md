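# Methods

`sersdx` re-implements, end to end, a diagnostic pipeline for Alzheimer's
disease built on surface-enhanced Raman spectroscopy (SERS) fingerprints of
cerebrospinal fluid (CSF): spectral cleanup, unsupervised clustering of
replicate fingerprints, a 1D convolutional classifier evaluated by
leave-one-group-out cross-validation with majority-vote scoring, and a
correlation analysis of the resulting diagnostic score against clinical
covariates. Because no patient spectra are publicly deposited for this kind
of study, the package ships a synthetic cohort generator that plants the
statistical structure the analysis assumes; every claim the test suite
makes is therefore a claim about recovery of planted structure, not about
real CSF.

## Spectral model and generator

Spectra live on a canonical grid of 550–1650 cm⁻¹ at 1 cm⁻¹ spacing
(1101 points), the acquisition range of the study being modeled; the
integer spacing makes "shift by one or two wavenumbers" an exact index
shift. A synthetic spectrum is

    I(ν) = baseline(ν) + Σₖ Aₖ·mₖ·eₖ·L(ν; cₖ, wₖ) + ε(ν)

with L a unit-height Lorentzian (the standard Raman band shape; default
half-width at half-maximum 8 cm⁻¹), Aₖ the band's base amplitude, mₖ the
class-template multiplier, eₖ a per-sample lognormal amplitude effect and
ε iid Gaussian noise. Six bands are planted — 850 (alanine),
870 (glutamate/serine), 1000 (phenylalanine), 1171 (tyrosine),
1465 (lipid) and 1555 cm⁻¹ (tryptophan) — the bands reported to drive
cluster formation in CSF fingerprints.

Defaults encode the study conditions: 80 spectra per mapping; replicate
mappings of one sample share the sample's effect vector (within-sample
dependence, the reason validation must hold out whole groups); sample-level
amplitude CV 2%; spectrum noise SD 0.05 (≈5% of a unit band); a small
positive quadratic baseline to exercise baseline correction. The
reproducibility design is 5 spectral classes × 1 sample × 3 replicate
mappings (15 groups); the diagnosis design is 26 samples (8 normal, 9
dementia, 5 FAD mutation carriers, 4 non-carriers — the scored cohort
sizes). Dementia modulates every band by ≥30% relative to normal; FAD
carriers sit 75% of the way toward the dementia pattern (pre-clinical
disease biochemistry), non-carriers 5% (essentially normal). These
interpolation fractions are a modeling choice — the real biochemical
distance of pre-symptomatic carriers from the demented pattern is unknown.

Clinical covariates are drawn per class from Gaussians with the published
group means/SDs (age, Aβ42, t-tau; biomarkers clamped at 1 pg/mL). A
latent severity score in [0,1] drives the cognitive scores monotonically
through the probit quantile of the class distribution — MMSE decreasing,
CDRSUM/CDRGLOB increasing — so severity ~ Uniform(0,1) reproduces the class
means/SDs while keeping score-versus-severity correlations plantable.
p-tau follows the linear link P = 0.1134·T + 35.28 plus Gaussian noise
whose SD is calibrated analytically (law-of-total-variance over the class
mix) so the pooled t-tau/p-tau Pearson correlation is ≈0.8883; the
positivity clamp attenuates the realized value slightly (≈0.87 at n = 2000,
within the ±0.05 band the recovery test uses).

What the generator does not emulate: substrate/plasmonic physics, cosmic
rays, detector drift, wavenumber miscalibration between sessions, band
shape changes (only amplitudes vary), and any overlap in class templates
beyond what the chosen multipliers imply. Passing tests show the pipeline
recovers structure of this kind at these effect sizes; they do not certify
performance on real CSF.

## Preprocessing

Per spectrum: asymmetric-least-squares baseline subtraction
(Eilers–Boelens Whittaker smoother, defaults λ = 1e5, p = 0.01,
10 reweighting iterations; the pentadiagonal system is solved by banded
Cholesky) followed by Savitzky–Golay denoising (window 11, order 3, which
preserves band positions). Per mapping: pointwise averaging into the sample
fingerprint, then integration normalization — division by the trapezoidal
integral over the grid, so every fingerprint integrates to one
(idempotent and scale-invariant). The original study delegated baseline and
noise removal to instrument software without describing the algorithms;
AsLS + Savitzky–Golay is the standard open replacement, applied per
spectrum before averaging. A stiff baseline (large λ) attenuates band
heights by only a few percent; the default λ trades a little attenuation
for tracking of curved fluorescence backgrounds.

## Clustering

Averaged, normalized fingerprints are treated as vectors (each wavenumber
one dimension, intensity the value); distances are Euclidean over the full
grid by default, with a peak-height variant (intensities at the six band
positions only) available. Agglomerative clustering uses complete linkage
by default — the method named for the published dendrogram — with single
and average selectable, since the study's text names both complete and
single linkage in different places. The merge sequence is scipy's; tests
check it against a brute-force O(n³) re-implementation. Replicate
concordance is 1.0 exactly when the flat clustering at k = number of true
samples equals the true replicate partition, and the adjusted Rand index
otherwise.

## Augmentation

Three operators, applied to training folds only and never across mapping
groups: (i) spectrum shift by ±1–2 grid steps (uniform over the four
non-zero shifts; vacated edge positions replicate the edge value);
(ii) additive Gaussian noise with SD = 5% of the spectrum's own intensity
SD; (iii) convex combinations of 2 spectra sampled without replacement from
one mapping, weights from a flat Dirichlet (a general-linear mode exists
behind a flag; convex weights keep intensities physical). The default
output/input ratio is 2; every synthetic spectrum carries provenance
(operator, parameters, source sites) and its source group's id, so group
integrity is auditable and the leakage guard in training can see through
augmentation.

## Classifier

A small 1D CNN implemented directly on numpy: [conv (valid padding) → ReLU
→ max-pool] blocks over the 1101-point fingerprint, flatten, one hidden
dense ReLU layer, softmax output. Training minimizes class-weighted
categorical cross-entropy (weights inversely proportional to class
frequency, mean 1 — the natural reading of a weighted-loss sum with an
8-versus-9 class balance) by Adagrad, with early stopping on the loss of a
held-out, group-respecting 10% validation split (whole groups held out; the
same dependence argument that motivates group-wise testing applies to
validation), restoring the parameters at the best validation loss.

Defaults: two conv blocks (8 filters, kernel 9; 16 filters, kernel 7),
pool 4, dense 64, learning rate 0.05, batch 64, max 40 epochs, patience 6,
min_delta 1e-3 nats. The architecture family follows the published
description (conv/ReLU/max-pool stacks into two dense layers); the exact
sizes were never published, so these are sized for single-core CPU
training: a full leave-one-group-out evaluation of the 26 × 80-spectrum
cohort (18 model fits after augmentation) completes in under two minutes.
Inputs are standardized per feature on the training set. All randomness
sits behind the config seed; single-threaded reruns are bit-identical.
Implementation notes: max-pooling is computed before ReLU (the two
commute for monotone activations) with a running elementwise maximum, and
the pooling gradient is routed by an equality mask — exact float ties
would share gradient but do not occur with continuous pre-activations.

## Evaluation protocol

Leave-one-group-out: one round per mapping group; the held-out group's
spectra are the test set, training uses all other normal/dementia groups
(augmented). FAD groups never enter any training set — the binary model is
trained on normal-versus-dementia only, carriers are expected to score as
diseased and non-carriers as normal. Since every FAD round would train on
the identical set, that model is fitted once and reused; under a fixed seed
this is the same as per-round retraining.

The vote score is 100 × (fraction of the group's spectra predicted as the
sample's clinically expected class). Anchoring to the expected class rather
than the modal class is deliberate: a two-class modal percentage can never
fall below 50, yet the published per-sample scores include 31.25 and 49, so
only the expected-class reading reproduces the printed tables; the modal
percentage is what the `predicted_label` field reports. Calls use the
50 threshold: above → correct, below → incorrect, exactly 50 →
indeterminate (counted as not correct; the boundary never occurs in the
published tables). Summaries report per-label n, correct calls, accuracy
and mean score at one decimal.

Spectrum-level leave-one-out (every spectrum held out once, group structure
deliberately ignored) is provided for completeness with a k-fold
approximation flag; it measures within-cohort spectral uniformity, not
generalization to unseen samples.

## Correlation analysis

The tau relation is fitted by OLS of p-tau on t-tau over complete cases.
Records missing exactly one tau are filled from the fitted line — a missing
t-tau by inverting it, T = (P − intercept)/slope, the literal reading of
"filling in from this correlation" (a refit of T-on-P is available behind a
flag); records missing both taus are excluded and reported, mirroring the
published handling of the one sample with no tau data at all. The
correlation matrix is pairwise-complete Pearson (Spearman behind a flag)
over score, Aβ42, t-tau, p-tau, MMSE, CDRSUM, CDRGLOB, age and sex (coded
F = 0, M = 1, an arbitrary declared convention); zero-variance variables
and pairs with fewer than three complete records are flagged NaN rather
than dropped.

## Problem sizes and numerical choices

The shipped experiments use the study-scale designs: 15 mappings × 80
spectra for the clustering experiment, 26 × 80 for the diagnosis pipeline,
n = 2000 subjects for the clinical-generator calibration checks.
Degenerate inputs are defined, not crashed on: constant spectra
baseline-correct to zero; normalization refuses non-positive integrals;
single-class training sets, cross-group combinations and test-group leakage
raise immediately. Dendrogram tie-breaks follow scipy's deterministic
order; with continuous synthetic distances ties have measure zero.

## Known limitations

The classifier's performance on the default cohort is effectively at
ceiling (every vote unanimous), because the planted class separation is
large relative to the noise; the published real-data scores spread widely
below 100, reflecting biological overlap the generator does not model.
Real-data quantities that depend on the unpublished patient spectra — the
leave-one-out accuracies, the tau regression coefficients as fitted to
patient data, and the score-versus-CDR correlations — are represented here
by recovery checks on planted structure and by recomputation of the
published summary tables, not by reproduction from raw data.
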