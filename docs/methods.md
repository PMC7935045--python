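# Methods

## Problem and scope

`fcmodes` implements a two-arm analysis relating resting-state functional
connectivity (FC) to behavior in a repeated-measures design (~23 subjects,
2–3 sessions of two 6-minute runs each, 180 volumes/run at TR = 2 s). The
static arm summarizes each subject-session by a full Pearson correlation
matrix over nodes, vectorizes its 96,141 unique edges (at the 439-node
parcellation) and reduces them with PCA. The time-varying arm fits a
K-state Gaussian hidden Markov model (HMM) to the concatenated,
PCA-reduced node signals and summarizes each subject-session by 17
features: fractional occupancy (FO) of the 12 states and 3 metastates plus
the mean switching rate across states and across metastates. Each arm is
related to behavioral factor scores through canonical correlation analysis
(CCA) with subject-grouped permutation inference. Because no real dataset
ships with the package, a synthetic generator with known ground truth
drives all tests.

## Preprocessing

Per run, the chain is: confound regression → 0.01–0.1 Hz bandpass →
per-session standardization, then concatenation across subjects. Confounds
are the 6 motion parameters plus mean white-matter and CSF signals,
expanded to 32 regressors (base, backward first difference with a zero
first frame, and both squared). Regression is ordinary least squares with
an intercept; rank-deficient designs fall back to the minimum-norm
solution (equivalent to dropping dependent columns). The bandpass is a
4th-order Butterworth applied forward-backward (`sosfiltfilt`), chosen
because the filter family/order is otherwise unconstrained and zero phase
preserves state timing. No scrubbing and no global-signal regression.
Framewise displacement is the sum of absolute backward differences of the
three translations (mm) plus the three rotations (radians) scaled by a
50 mm sphere radius; FD(1) = 0.

## Gaussian HMM

Observations x_t in feature space follow N(mu_k, Sigma_k) given state
s_t = k; states evolve by a first-order chain with row-stochastic
transition matrix Theta. Chains restart at each subject-session boundary
(runs are concatenated within session, so blocks are sessions). Inference
is variational Bayes with conjugate priors — Gaussian–Wishart on each
state's mean/precision, Dirichlet(1) on each Theta row and on the initial
distribution; prior strength defaults to one pseudo-observation because
nothing stronger is warranted. The variational free energy is computed as
the sum over blocks of the forward-pass log-normalizer under expected-log
parameters minus the parameter KL terms; it is nondecreasing across
iterations and checked to 1e-6 in the suite. Message passing uses
per-timestep rescaling with a per-row log shift, numerically equivalent to
log-domain propagation (finite for emission log-likelihood ranges of
1e±30). Initialization is k-means on a ≤5,000-row subsample; 5 restarts by
default, best final objective kept; convergence at relative objective
change < 1e-5 or 500 iterations. Point estimates reported are posterior
means; full covariances, with 1e-6·trace/dim jitter in the EM mode (an
exact maximum-likelihood Baum–Welch implementation kept for oracle
testing). State labels are arbitrary; evaluation against ground truth
aligns labels by maximum-agreement assignment. State/node indices are
0-based internally, 1-based in reported column names.

## State dynamics

FO is the block mean of the posterior state probabilities. Switching rate
is sum_t sum_k |P[t+1,k] − P[t,k]| divided by the number of timepoints in
the block; the absolute value is required (the signed sum telescopes to
~0) and the denominator is configurable (`timepoints`, the default,
following the definition literally, or `transitions`). Metastates come
from single-linkage agglomerative clustering of the Euclidean distances
between transition-matrix rows, cut at 3 clusters (configurable); metastate
time courses are column sums of members, and metastate FO/switching rate
use the same definitions. The spatial overlap index thresholds a state
activation map to the top 40% of positive-valued nodes by value and top
40% of negative-valued nodes by magnitude (counts rounded to nearest, ties
broken by node index — a choice the data rarely exercises) and divides the
overlap with a network by the network's size; it is invariant to positive
rescaling of the map. Motion QC correlates each of the 17 features with
session-specific mean FD across subjects (17 × 3 = 51 tests) and adjusts
jointly with Benjamini–Hochberg FDR, the standard choice where only "FDR"
is specified.

## Behavioral factor analysis

The 31 measures (6 spatial working memory, 6 digit-symbol substitution,
3 Stroop, 4 color working memory, 8 visual-analog-scale, 3 Barratt
impulsiveness subscales, 1 box completion) are standardized and factored
by maximum likelihood (scikit-learn's `FactorAnalysis`), then rotated with
promax at the conventional power 4 (varimax with Kaiser normalization
first, oblique target fit second). Scores use the regression (Thurstone)
method F = Z R⁻¹ (L Phi). Eight factors by default. Heywood cases
(communalities > 1) warn and are clipped in the reported uniquenesses.
Promax and the scores are implemented in-package because no installed
library provides oblique rotation.

## CCA and inference

The solver whitens each side by the symmetric inverse square root of its
covariance (eigendecomposition; eigenvalues below 1e-10 of the maximum are
dropped, giving automatic rank reduction) and takes the SVD of the
whitened cross-covariance; signs are fixed so each mode's largest-|weight|
X entry is positive. The dynamic arm uses the 17-column feature matrix
directly (no PCA needed at that dimensionality); the static arm uses the
top 13 edge PCs by default.

Permutation inference respects the repeated-measures structure: all
sessions of a subject form one exchangeability block, and blocks exchange
only among blocks with equal session counts so the permuted design stays
row-aligned. Mode k's p-value compares its observed correlation to the
permutation distribution of the k-th correlation with the add-one
convention p = (1 + #{perm ≥ obs}) / (1 + n_perm); a max-statistic option
gives family-wise control. Default 10,000 permutations.

Cross-validation draws 80% of subject blocks, fits CCA on those rows and
projects the held-out rows with the training weights (refitting on ~13
rows would be ill-posed); the fold statistic is the held-out variate
correlation per mode. Its null is rebuilt with the same full-design
grouped permutation, refitting the training CCA on permuted data and
recomputing the held-out correlation. Permuting only the held-out blocks
is not viable: a 20% held-out set from the 18×3 + 5×2 design has ~5
blocks, and equal-session-count exchange then admits as few as 12 distinct
rearrangements, putting the attainable p floor above the 0.05 test level
in roughly a quarter of folds. Default 1,000 folds.

Post hoc loadings are Pearson correlations of each original variable with
its own side's variate. The stability sweep re-runs factor fitting, PCA
and CCA over a grid of (number of factors 1–9) × (number of PCs 1–20) and
reports the pairwise Pearson similarity of the resulting 31-measure
loading vectors; configurations that fail to fit are recorded as missing.

## Synthetic generator

The generator emulates the study shape: 23 subjects (18 with a third
session), 2 runs × 180 timepoints per session at TR = 2 s, 12 states with
a 2/9/1 block-structured transition matrix at 0.9 within-block mass, and a
31-measure behavior table with an 8-factor structure (loadings 0.8 on the
assigned factor, uniqueness 0.36·noise_sd²). State means sit on a random
±1 sign grid scaled by `state_mean_scale` (separation enforced to at least
p/4 differing coordinates) with shared spherical covariance noise_sd²·I,
so separability is one knob. One behavioral factor is a
`behavior_coupling`-weighted mixture (default 0.85) of the standardized
planted FO combination and fresh noise, planting a single canonical mode
at exactly that correlation at the subject-session level. Motion traces
are 6-parameter random walks (translation step SD 0.03 mm, rotation step
SD 4e-4 rad, 1% spike probability) calibrated to a mean FD near 0.14 mm.
Phase-randomized surrogates preserve each node's amplitude spectrum
exactly with independent phase draws per node.

What the generator does not emulate: hemodynamic convolution,
scanner/physiological artifacts, spatially structured state covariances,
non-Gaussian behavioral measures (the distributional form of the real
battery is unknown; Gaussian factors + Gaussian noise are assumed), and
real session-to-session drift. Passing tests therefore certify the
statistical machinery under its own assumptions, not performance on real
fMRI data.

## Problem sizes used by the tests and acceptance script

Chosen as the package's standard check sizes: HMM recovery uses 4
well-separated states over 20 chains × 300 frames × 8 features with 3
restarts; null calibration uses 500 replicates of the 23-subject grouped
design with 200 permutations each; planted-mode cross-validation pools 67
folds × 200 permutations over three generated datasets (realization noise
of a single 23-subject draw is otherwise comparable to the quantity being
estimated); the full permutation test uses 999 permutations; the
end-to-end feature-count run keeps the 12-state design at a small node
count. The forward–backward oracle enumerates all 3⁶ paths at T = 6.

## Known limitations

- The VB free energy is exact for the conjugate family used, but the
  reported point estimates are posterior means, which can differ slightly
  from maximum-likelihood estimates on small data.
- Factor-analysis extraction assumes the standardized-correlation metric;
  with very few rows (n ≈ 64) promax solutions are noisy, which is
  faithful to the emulated study scale.
- The grouped permutation scheme conditions on the observed session-count
  composition; designs where every block size is unique admit no exchange
  and are rejected rather than silently unrestricted.
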