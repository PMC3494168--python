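# Methods

This note records the models the package implements, the assumptions and
numerical conventions behind them, what the synthetic data generator does
and does not emulate, and the design choices made where the published
procedure left the design open.

## Pipeline model

The package targets the standard two-stage diagnostic design for
resting-state fMRI: a feature-creation stage that compresses each
subject's 4-D scan, and a learning stage that fits a classifier on the
compressed features (plus optional phenotypic covariates).  All
operations act on a subject's scan as an `L × W × H × T` real array with
a voxel size in mm and a volume time (TR) in seconds.

### Temporal standardization

Multi-site cohorts mix volume times (1.5, 1.96, 2.0, 2.5, 3.0 s in the
motivating cohort).  Every scan is truncated to a common 185 s duration —
the shortest scan time across sites — and linearly interpolated to a
0.5 s volume time (2 Hz), giving exactly 370 samples at times
`0, 0.5, …, 184.5 s`.  Up-sampling to 0.5 s rather than resampling to an
intermediate rate (e.g. 2.0 s) avoids interpolation error where native
volume times are integer multiples of 0.5 s, and resampling a 2 Hz scan
at 2 Hz is the exact identity.  Two conventions are ours: the *first*
185 s are kept (the truncation anchor is not specified anywhere we could
find, and a leading window is the conventional choice), and the output
grid starts at t = 0 inclusive and excludes t = 185 s, which is the only
choice that yields the canonical 370 points.  No high-pass temporal
filtering is ever applied: resting-state analyses treat the 0.001–0.1 Hz
band as signal, and removing it would discard exactly the components the
features are built from.

### Spatial block averaging

Each `k × k × k` sub-volume is replaced by its mean intensity at every
time point; partial blocks at the grid edge are dropped, so the output
grid is `(⌊L/k⌋, ⌊W/k⌋, ⌊H/k⌋)` and the voxel size scales by `k`.  With
k = 3 the full-resolution 57×67×50 grid becomes 19×22×16 = 6688 voxels.
Averaging conserves the grand mean over the retained region and commutes
with everything linear downstream.

### BOLD signal normalization

Three methods are implemented (`psc`, `zn1`, `zn2`):

* percent signal change `(x − μᵢ)·100/μᵢ` and per-voxel z-scoring
  `(x − μᵢ)/σᵢ` normalize each voxel by its own temporal statistics;
* global z-scoring (`zn2`, the default) uses the mean and standard
  deviation over the subject's *entire* scan, `(x − μ)/σ`, leaving the
  scan with global mean 0 and standard deviation 1.

`zn2` removes per-subject gain and offset — the component of between-site
variation introduced by scanner configuration — while preserving the
*relative* spatial structure that the per-voxel methods destroy.  All
standard deviations are population-style (divide by the count); the
convention is switchable (`ddof`) and irrelevant to any downstream ratio.

### Masking

Voxels outside the brain are removed *after* normalization.  After `zn2`
on data whose out-of-brain voxels sit below the scan mean, in-brain
voxels have positive temporal means and out-of-brain voxels negative
ones, so the default mask is `mean_t(x) > 0` on the averaged grid; an
explicit NIfTI mask can override it.  The masked scan is a `V × T′`
matrix in fixed raster order (x fastest, then y, then z) with a
row → grid-coordinate index map, so the concatenated layout is identical
across subjects.  Masking *before* normalization is a known accuracy
hazard (it discards the out-of-brain intensities that carry site
information into the global statistics), so the pipeline enforces the
order and requires an explicit `force` flag to override.  Note the
published figure of 3584 in-brain voxels on the 19×22×16 grid depends on
a mask whose construction was never specified; it is not recomputable and
is not asserted anywhere.

## Feature creation

Seven processes, all with deterministic out-of-sample projection.

**FFT magnitudes.**  For an even `T′`-sample waveform the one-sided DFT
magnitudes of bins `1 … T′/2` are returned (Nyquist included, DC
excluded).  The DC bin carries only the waveform mean, which `zn2` has
already standardized; excluding it is also the only convention under
which 370 samples yield the canonical 185 magnitudes.  (The often-quoted
per-subject feature count for a 3584-voxel mask is therefore
3584 × 185 = 663,040; the widely printed figure 633,040 is an arithmetic
slip in the source material.)  Phase is discarded, which makes the
features invariant to temporal offsets of the underlying oscillations.

**PCA-t.**  Every voxel waveform of every subject is one row of the
`NV × T′` matrix `X_t`.  The `T′ × T′` covariance of the column-centered
matrix is eigendecomposed directly.  Projection maps each subject's `V`
waveforms onto the top-m eigenvectors and concatenates voxel-major
(`V·m` features).  `m` may be a count or a variance fraction (smallest
count reaching the fraction); on realistic waveform data m = 2 captures
over 99.9 % of the variance.

**PCA-st (dual trick).**  Each subject's concatenated waveforms form one
row of `X_st ∈ ℝ^{N×VT′}`.  Because `VT′ ≫ N`, the `VT′ × VT′` covariance
is never materialized: the `N × N` Gram matrix `G = X̄X̄ᵀ` of the
column-centered data is eigendecomposed, and each dual eigenvector `u_i`
with Gram eigenvalue `ν_i > 0` maps to the unit-norm primal eigenvector
`e_i = X̄ᵀu_i/√ν_i`.  Covariance eigenvalues are reported as `ν_i/N`
(population convention; eigenvectors and variance fractions are
invariant to this choice).  Scores are `Z(j,i) = ⟨x_j − mean, e_i⟩`.  The
source text projects `X_st` without stating whether rows are centered; we
subtract the training column means, consistent with the centered
covariance the dual trick diagonalizes.  Centering makes the Gram matrix
rank ≤ N−1, which is why a full-rank linear fit retains N−1 components
where the kernelized variant retains N.

**kPCA-st.**  The RBF kernel `k(x_i,x_j) = exp(−‖x_i−x_j‖²/2σ²)` with
σ = 150 by default is evaluated over training subjects (strictly positive
definite for distinct rows — all N raw-kernel eigenvalues are positive),
centered in feature space via `K = K̃ − 1_N K̃ − K̃ 1_N + 1_N K̃ 1_N`
(`1_N` the matrix of entries 1/N), and eigendecomposed.  Training scores
follow the literal projection `Z = K·E` (column i equals `λ_i e_i`); the
textbook `1/√λ` score normalization is available behind a flag but is not
the default — fidelity to the published four-step procedure comes first.
Out-of-sample rows are centered against the *training* kernel,
`k = k̃ − 1′_t K̃ − k̃ 1_N + 1′_t K̃ 1_N`, which reproduces training score
rows exactly when a training subject is projected.  In the large-σ limit
the centered RBF kernel approaches the linear Gram matrix scaled by
1/σ², so kPCA-st scores correlate perfectly with PCA-st scores — a
property the tests exploit as an independent check.

**Numerical conventions** (shared): eigenvalues are clipped at zero and
treated as zero below `1e-10 × λ_max`; requested component counts
exceeding the positive-eigenvalue count are clipped with a logged
warning; every eigenvector is sign-canonicalized (largest-magnitude entry
positive) so scores are reproducible across runs and eigensolver
backends; degenerate inputs (rank-0 covariance, zero denominators in
normalization) raise typed errors naming the offending statistic.

## Evaluation

Fifteen feature sets per setting: phenotypic-only, plus imaging-only and
imaging+phenotypic for each of the seven processes.  The classifier is a
linear-kernel SVM with C = 1 (the published work states only "linear
SVM"; C is exposed in config).  The three-class setting
(control / ADHD-combined / ADHD-inattentive) uses one-vs-one voting; the
two-class setting collapses the subtypes to a single ADHD label.
Imaging features enter the classifier unscaled by default, matching the
literal score definitions; a standardization flag is future work's
option, not the default.

**Folds.**  Fold assignment is stratified by (class, site): strata are
shuffled and dealt round-robin into folds with a counter rolling across
strata, so fold sizes differ by at most one and each stratum is spread as
evenly as its size permits.  The same folds are reused for every feature
set, making paired fold-wise comparisons valid.

**Leakage.**  Per-subject preprocessing uses no cross-subject statistics
and is applied once.  Everything cross-subject — the auto mask
(intersection of training subjects' sign masks), the PCA/kPCA fit, IQ
imputation and phenotype standardization — is fitted per fold on training
subjects only.  The fitted state of every fold is hashed, and tests
verify the hash is invariant to arbitrary perturbation of test subjects.
A transductive mode fits the mask and reduction once on all subjects
(classifier still fold-honest), reproducing the protocol reading in which
the reduction saw the whole cohort before cross-validation; per-fold
fitting is the default.

**Phenotypes.**  Age and the three IQ scores (verbal, performance, full)
are standardized to training mean 0 / sd 1, with missing IQ imputed by
the training-column mean first; gender is binary; site is one-hot over
training sites (unseen test sites encode as all-zero with a warning).
Handedness is excluded from the default phenotypic set and available via
a flag — the published feature list omits it even though the data carry
it.  The standalone `impute_iq` implements the whole-table mean rule for
use outside cross-validation.

**Comparisons.**  `compare_methods` runs a two-sided paired test over the
per-fold accuracy differences — paired t-test by default, Wilcoxon
signed-rank as an alternative; the test behind the published p-values is
unnamed, so the family is configurable.  Every report carries the caveat
that overlapping training sets make fold-wise standard deviations
underestimate the true prediction-error variance.

**Baselines.**  The majority-class baseline is `100 · max_c n_c / N`.
From the per-site count tables bundled with the package this gives
64.22 % for the 668-subject training cohort and 54.97 % for the
171-subject holdout cohort.  One row of the training table as circulated
is internally inconsistent (its class entries sum to 28, not the stated
38); the package reconstructs that row as 22/16/0 — the unique values
consistent with both the row total and the printed class totals
(429/141/98).

## Synthetic data: what it emulates, what it does not

The generator produces multi-site cohorts on a desk-scale 12×12×10 grid
(full 57×67×50 supported) with: two sites at 2.0 s and 2.5 s volume times
by default (any of 1.5/1.96/2.0/2.5/3.0 supported); a block-aligned
centered "brain" box with baseline +10 inside and −10 outside, so the
sign-of-mean mask is exactly recoverable; an optional per-site gain
factor emulating scanner magnitude differences (removed by `zn2` by
construction); class signatures as low-frequency sinusoids added to a
central in-brain block, with default frequencies 4/185, 9/185, 15/185 Hz
for control/combined/inattentive — inside the 0.001–0.1 Hz resting band,
below every site's Nyquist frequency, and exact multiples of the 1/185 Hz
resolution of the standardized window so planted power lands in single
DFT bins; a random phase per subject so the diagnostic information lives
in spectral magnitudes rather than raw waveforms; and i.i.d. Gaussian
voxel noise (sd 1.0 by default; the published material makes no claim
about noise, and an i.i.d. model suffices for parameter-recovery
testing).  Scans sample times `0 … ceil(duration/TR)·TR` so the sampled
span covers the full stated duration at every TR.  Phenotypes mimic a
mostly-adolescent cohort (IQ ~ N(110, 14), 10 % missing at random) and
are uninformative about diagnosis unless a class-conditional Full-IQ
shift is requested.

Not emulated: hemodynamics, spatial autocorrelation beyond block
structure, motion artifacts, anatomical templates, slice-timing effects,
and realistic between-site covariate shift.  Passing tests therefore
demonstrate that the pipeline's arithmetic and its leakage discipline are
correct and that planted spectral class structure is recoverable under
the stated conditions — not that any particular accuracy would be reached
on real clinical data.

## Problem sizes and known limitations

* Tests and the acceptance script run at desk scale: 12×12×10 grids
  (4×4×3 averaged, 4 in-brain voxels), cohorts of 10–60 subjects, 50
  randomized dual-vs-primal instances with N ≤ 8 and VT′ ≤ 40.  The
  full-resolution grid appears only in dimensional bookkeeping checks.
  These sizes are the package's chosen test conditions; all operators are
  vectorized and run at full scale.
* The linear SVM at C = 1 underfits when both the cohort and the kPCA
  score scale are very small (≲ 15 subjects at desk scale): separable
  classes can then fall to majority-class prediction because the margin
  penalty dominates the hinge loss.  This is a property of the
  classifier's fixed regularization, not of the reductions; recovery
  tests use cohorts of 20+ subjects where the published protocol's C = 1
  behaves as intended.
* Linear interpolation of a sinusoid sampled at 2.0–3.0 s introduces
  slight harmonic distortion, so spectral leakage off the signature bins
  is zero only for cohorts generated natively at 0.5 s; recovery tests at
  other TRs rely on the (large) magnitude contrast, not exact
  bin-sparsity.
* Holdout evaluation assumes the holdout cohort shares the training
  grid; site-harmonization beyond `zn2` and reproduction of published
  real-data accuracies are out of scope.
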