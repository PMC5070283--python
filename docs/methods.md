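# Methods

This note documents the models, numerical choices and limitations behind
`mmfnc`, in the order the pipeline runs.

## Data model and conventions

All connectivity features live in "pair space": the row-major upper
triangle (i < j) of a symmetric C×C matrix, giving C(C−1)/2 features. One
ordering is used everywhere — static features, windowed stacks, state
centroids — so that fused feature matrices can never silently misalign.
Timecourses are exchanged as TSV tables (rows = samples, header =
component ids); results as JSON with sorted keys, so identical inputs give
byte-identical outputs. Component identities are opaque strings; no
anatomical meaning is attached or needed. All downstream statistics are
correlation-based and therefore invariant to per-component affine
rescaling of the timecourses (asserted by test).

## Synthetic cohorts

The generator emulates the study design the pipeline targets: two groups
(default 46 SZ / 45 HC), one fMRI session (T = 149 samples, C = 38
components, effective sampling 0.5 Hz) and five MEG envelope bands
(T = 300, C = 32, 1 Hz). Per modality/band it draws a low-rank-plus-diagonal
random correlation matrix as the healthy-group static model; the patient
group's model perturbs chosen pairs by a signed `delta_r` and is projected
back to the nearest SPD correlation matrix (eigenvalue clipping at 1e−6,
re-normalization to unit diagonal). Default effects sit in fMRI, delta,
alpha and beta, and deliberately *not* in theta and gamma, so a correct
pipeline should classify those two bands at chance from static features.
Pair indices are arbitrary; no anatomical claim is made.

Dynamics are Markov-switching Gaussian covariance regimes: each subject
follows a first-order Markov chain over k states (default 5 per group,
stay probability 0.9, uniform switching, hence a uniform stationary
distribution), and each sample mixes a stationary draw from the static
model with a draw from the active state's covariance
(`mix_dynamic = 0.5` variance share). State correlation matrices are built
as SPD-repaired (static + deviation): planted static effects therefore
survive inside every state, a single zero-deviation state reproduces the
static model exactly, and the long-run correlation approaches the group
static model. Group differences in dynamics come from a
`state_divergence` knob in [0, 1]; the patient group's deviation patterns
are *mean-matched* to the healthy group's, so divergent states change
which connectivity configurations occur without shifting the long-run
(static) correlation — a band can carry dynamic group structure while
remaining a static null. Setting divergence to 0 makes the two groups'
state sets identical (a full null for calibration tests).

An AR(1) low-pass (unit-variance-preserving, coefficient 0.6 for fMRI to
mimic hemodynamic sluggishness, 0.3 for the 1 Hz MEG envelopes) smooths
each series; the filter preserves the stationary cross-correlation
structure. What the generator does *not* emulate: biophysical BOLD or
neural-mass dynamics, spatial (voxel-level) structure beyond the group-ICA
test fixtures, scanner drift/physiological confounds, and non-Gaussian
heavy-tailed noise. Passing tests therefore demonstrate correctness of the
estimation machinery under the pipeline's own assumptions, not performance
on real recordings.

## Group spatial ICA (optional stage)

Subject data (T×V) are reduced by temporal PCA (economy SVD), stacked, and
reduced again with an EM algorithm for PCA whose per-iteration explained
variance is monotonically non-decreasing; iteration stops when the
subspace projector stops moving (Frobenius change < 1e−12, max 5000
iterations), after which the basis is rotated to principal axes. Infomax
ICA uses the natural gradient with a logistic nonlinearity on whitened
data, block updates (size 128) in a seed-deterministic order, initial
learning rate 0.01, annealing ×0.9 on blow-up (non-finite or exploding
weights, retried from the pass start), a gentle ×0.995 per-pass decay, and
stops at a relative per-pass weight change below 1e−7 or 512 passes.
Stability follows the repeated-run recipe: 20 runs by default, run-wise
components clustered by absolute Pearson correlation of their maps
(average-linkage agglomerative, cut at C_ic clusters); cluster quality =
mean intra-cluster minus mean extra-cluster similarity, and the returned
decomposition is the run closest to the cluster centrotypes.
Back-reconstruction is dual (spatial-temporal) regression — least squares
of subject data on the group maps — chosen over alternatives for its
simple, testable contract.

Component screening uses two spectral rules on Welch spectra: the
low-frequency/high-frequency power ratio (integral below 0.10 Hz over the
integral in 0.15–0.25 Hz; threshold default 2.0) and the dynamic range
(peak power minus the minimum power to the right of the peak; threshold
default 0, i.e., informative but permissive). Expert visual criteria are
out of scope. The whole ICA stage is optional: the connectivity stages
accept externally supplied component timecourses directly.

## Static FNC

Timecourses are despiked first: samples deviating more than c = 4
(MAD-based, Gaussian-consistent ×1.4826) sigmas from a window-5 running
median are replaced by that median; a genuinely smooth series is left
untouched and constant series pass through. Static FNC is zero-lag
Pearson correlation over the full series; a maximum-lagged variant
(signed correlation of largest magnitude over ±L samples, default off) is
available because lagged robustness is sometimes preferred. Fisher z uses
arctanh with |r| clipped at 1 − 1e−7 to keep degenerate synthetic inputs
finite. Group testing is a Welch (unequal-variance) two-sample t-test per
pair — the groups are independent samples — with Benjamini–Hochberg
step-up control at q = 0.05. If no pair survives, the selector falls back
to the single smallest-p pair with a warning so downstream classifiers
always receive at least one feature; with q = 0 this fallback is the only
path. Selection is strictly per-fold on training subjects.

## Dynamic FNC

The taper is a width-31 rectangle convolved with a unit-sum Gaussian
(σ = 3 samples, truncated at ±3σ), center-cropped and renormalized to sum
w; window starts advance by 1 sample and only full windows are used, so
N = ⌊(T−w)/step⌋ + 1 (119 windows at T = 149; 270 at T = 300). The same
width is used for fMRI and MEG by default (configurable per run). Each
window's taper-weighted covariance (weight-sum normalization) is converted
to correlation scale and passed to the graphical LASSO
(`sklearn.covariance.graphical_lasso`, which penalizes exactly the
off-diagonal precision entries); solving on the correlation scale makes
the penalty act uniformly across pairs and keeps the coordinate-descent
solver well conditioned — heterogeneous window variances otherwise make it
fail occasionally, and a small ridge ladder (1e−6 … 1e−3) is the second
line of defense. λ = 0 short-circuits to a direct (ridge-stabilized)
inverse. The regularized covariance Θ⁻¹ becomes a correlation matrix and
is Fisher-z transformed; those vectors are the windowed features.

The penalty is chosen per subject: windows are split into 3 contiguous
blocks (contiguity limits temporal leakage between overlapping windows);
for each grid value (default 10 points log-spaced in [0.01, 1]) the model
is fit on the mean training-block covariance and scored by Gaussian
log-likelihood of the mean held-out covariance; ties go to the larger,
sparser penalty.

States are k-means centroids (k-means++ init, 10 restarts, Euclidean
distance in Fisher-z pair space; cosine/correlation variants are realized
by row normalization before clustering), fit per group on training-subject
windows only. The number of states can be validated by the elbow of the
cluster validity index — mean within-cluster distance over mean
between-centroid distance — operationalized as the k with the largest
discrete second difference of the index over the k grid; a monotone index
with no positive curvature returns the smallest k with a warning. Each
subject is reduced to 2k features: per window, ordinary least squares of
the (pair-mean-centered) window vector on the 2k mean-centered centroid
columns, no intercept, betas averaged over windows; a rank-deficient
centroid design falls back to a 1e−6 ridge with a warning. Centroid
blocks are ordered by sorted group label (HC block first), so feature
positions are stable across folds.

## Classification and ensembling

Leave-one-out cross-validation iterates subjects in sorted-id order.
Anything fold-dependent — static pair selection, state centroids — is
re-fit inside each fold from training subjects only; per-subject
connectivity (which never looks at other subjects) is computed once.
Features are standardized with training-fold statistics; zero-variance
features are dropped with a warning. LDC uses the unregularized linear
discriminant when the training problem is well posed and the Ledoit–Wolf
shrinkage solver when features ≥ subjects (the common case here); NBC is
Gaussian Naive Bayes with a 1e−9 variance floor; nSVM is an RBF-kernel
soft-margin SVM with C = 1 and γ = 1/(d·Var) on the standardized training
fold. Accuracy tables report percent per classifier plus the mean and
between-classifier standard deviation.

Fusion: (1) feature concatenation of fMRI + one band (selection applied
per source, then columns concatenated with provenance retained), and
(2) equal-weight majority voting across per-band predictions within one
classifier — a 3-member static panel (fMRI+delta/alpha/beta) and a
5-member dynamic panel (fMRI+each band). Panels are odd-sized by design;
for generality ties are still defined: highest mean member confidence
(max posterior where available, logistic-squashed |decision margin| for
the SVM), then fixed class order (HC first), with a tie flag returned.
Cross-classifier voting exists but is off by default.

## Seeds and determinism

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage and per-fold seeds from a master seed by fixed offsets, and the
orchestrated run writes a manifest with the seeds, effective parameters
and SHA-256 hashes of all artifacts. Repeat runs with the same seed are
byte-identical (asserted by test).

## Problem sizes used in tests

The test and acceptance suites run the full machinery at reduced problem
sizes chosen to keep the suites fast while leaving every statistical check
well powered: cohorts of 16–40 subjects with 8–10 components and 100–120
samples for classification checks; 200 replicate null cohorts for FDR
calibration; 10-seed replicates for state recovery (5 planted states at
≥5× separation), elbow selection (4 states) and ICA recovery (5 Laplacian
sources, 10 000 samples). The full study shape (91 subjects, C = 38/32,
all five bands) is exercised for the generator and the window/pair
arithmetic; classification at that scale runs through the same code paths
unchanged.

## Known limitations

* The synthetic generator's realism limits (above) mean reported
  accuracies characterize the machinery, not any real cohort.
* The graphical-LASSO windows are solved on correlation scale; precision
  values are therefore in correlation units (the pipeline consumes only
  the derived correlations).
* The ICASSO similarity uses map correlations only (no timecourse
  similarity term), and the infomax implementation is the logistic
  (super-Gaussian) variant — appropriate for sparse spatial maps, not for
  sub-Gaussian sources.
* With only two grid points or fewer than three k values, elbow selection
  degenerates to the smallest k (with a warning).
* The group-ICA stage, when used, is fit once on all subjects before
  cross-validation, which can optimistically bias accuracy; per-fold
  refitting is available for small problems via the library API.
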