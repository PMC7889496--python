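# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the limits of what the test suite can show.

## Task model

Three one-armed bandits (A, B, C) pay binary outcomes coded y ∈ {−1, +1}.
Each latent good-outcome probability lives on {0.1, 0.9} and flips state
with a fixed per-trial switch probability, evaluated independently on every
trial of a block (no refractory period — the stated parameter is an average
per-trial rate, and a memoryless flip is the simplest process with that
property). A and B share one latent process: identical in +Corr blocks,
mirrored (p_A + p_B = 1) in −Corr blocks; C has its own process. Each
process starts a block at 0.9 or 0.1 with equal probability. Stimulus order
is a seeded uniform shuffle constrained to exactly `trials_per_stimulus`
presentations per stimulus, with no further run-length constraints.

Session configurations:

| setting              | trials/stimulus | block length | switch prob | blocks |
|----------------------|-----------------|--------------|-------------|--------|
| scanner              | 10              | 30           | 0.15        | 8 (2 runs × 4 types) |
| pre-scan reminder    | 14              | 42           | 0.15        | 4      |
| online training      | 20              | 60           | 0.05        | 8      |

The pre-scan switch probability is not separately specified anywhere we
model it from; we use 0.15 because pre-scan blocks are short like scanner
blocks and the faster rate exists precisely to compensate for short blocks.
On training days 3–4 the last 15 trials of each block withhold outcome
feedback on rejected trials; the generator marks the tail and the feedback
flag is resolved once choices exist.

Block order is counterbalanced across simulated subjects with a 4×4 Latin
square over the four block types (the counterbalancing scheme itself is a
free design choice; a Latin square guarantees each type appears in each
serial position equally often across groups of four subjects).

Trial timing for onset generation: 1.5 s pre-choice window, a lognormal
response time (median 1 s, σ = 0.35), 0.5 s choice highlight, a
choice–outcome delay drawn from an exponential with mean 4.5 s truncated to
[3.5, 5.5] s (rejection sampling), 1 s outcome display, and an intertrial
interval from an exponential with mean 3 s truncated to [2.5, 4] s. Onsets
restart at zero per block because all downstream GLMs are per block.

## Learning models

The STRUCT learner keeps beliefs g ∈ [−1, 1] per stimulus, reset to 0 at
every block start. After outcome y on presented stimulus X:

    g_X ← (1 − α) g_X + α y
    g_Y ← (1 − α |H_XY|) g_Y + α H_XY y   (Y ≠ X)

Both updates are convex combinations of a current belief and ±y, which
proves |g| ≤ 1 for all time (the suite also fuzzes this). H_XY = ±1 makes
the two beliefs exactly (anti)symmetric for all time when they start equal.
NAÏVE is STRUCT with all H pinned at 0, so the two likelihoods coincide
exactly when STRUCT's cross-terms are 0 — a machine-precision identity used
as a regression test. Choices follow P(accept) = 1/(1 + e^{−βg}).

Parameter bounds: α ∈ [0, 1], β ∈ [0, 8], H ∈ [−1, 1]. Fitting minimizes
the negative log likelihood of the observed accept/reject sequence
(belief updates are skipped on feedback-less trials; the choices on those
trials still count) with L-BFGS-B from 10 Latin-hypercube starting points
(seeded), convergence tolerance 1e−6 on the NLL, best optimum kept. A
probability floor of 1e−12 inside the log guards β at its upper bound.
Two pooling conventions are exposed: per structure (all blocks of one
correlation sign concatenated — the default for downstream regressors) and
per block type (the cross-validation training sets).

Identifiability note: a choice sequence with no information content has two
equivalent maximum-likelihood ridges (β → 0 at any α, and α → 0 at any β);
recovery tests treat either as a correct null fit.

Derived per-trial quantities (GLM regressors): the pre-update belief of the
presented stimulus ("stimulus value"); the outcome prediction error
ε = y − g; the chosen-action value (g on accept, −g on reject — a confident
rejection is a valuable action); and the "correctness" prediction error,
|ε| signed positive when outcome and choice are congruent.

## Model comparison

Per subject, each model is fitted to each of the four block types and
evaluated on all four, giving a 4×4 test-NLL matrix per model. Three masks
carry the hypotheses: within-structure off-diagonal, across-structure, and
the diagonal. Group tests are paired t-tests on per-subject mask-sum
differences; exactly-zero-variance contrasts are flagged as degenerate and
reported with limiting p values rather than NaN. Divergent-trial analysis
selects trials where the two models' beliefs have opposite signs (a model
predicts accept iff its belief is positive; exact zeros are excluded).
Because the criterion behind the formal model comparison is not pinned
down externally, both AIC (2k + 2·NLL) and BIC (k·ln n + 2·NLL) are
reported, per subject and as cohort sums; cross-validation matrices are
exported both summed and averaged over subjects.

## GLMs

Regressors are delta functions at event onsets, optionally scaled by a
parametric modulator that is mean-centered within block (the conventional
choice; it decorrelates the parametric column from its main effect), then
convolved with a double-gamma HRF and resampled to the TR grid (TR =
1.235 s). The HRF is parameterized by its peak delay (default 6 s; 8.5 s
for the slow medial-prefrontal variant); the undershoot delay scales
proportionally (16 s at a 6 s peak) so a delay change shifts the whole
response. Gamma shapes use delay/dispersion + 1 so the kernel mode lands
exactly on the configured delay; the kernel is unit-peak normalized.

Each block contributes its own columns plus an intercept (multi-block
designs are block-diagonal). Six smooth random series stand in for motion
nuisances on synthetic runs; a discrete-cosine drift basis with a 100 s
cutoff is available but disabled by default on synthetic data (the phantom
has no drift). Event types absent from a block (e.g. no rejections)
contribute no column. Fits are voxelwise OLS with an explicit rank check
that names offending columns.

Canonical layouts: GLM1 (related-pair mains at stimulus and outcome times,
chosen-action-value parametrics from both models entered *unorthogonalized*,
C mains, accept/reject button regressors); GLM2 (per-stimulus mains — the
RSA pattern GLM); GLM2a (related pair collapsed onto one regressor); GLM3
(outcome mains plus the STRUCT correctness-PE parametric at related-pair
outcome times).

## RSA and group inference

Within each searchlight (the k = 100 nearest in-mask voxels by 3-D
Euclidean distance), condition coefficients are spatially prewhitened by
the inverse matrix square root of the GLM residual covariance, shrunk
toward its diagonal with fixed intensity 0.4 (config-exposed, with an
analytic "auto" option). A fixed intensity was chosen because the
data-driven coefficient costs a second O(T·V²) pass per searchlight and the
downstream statistics are permutation-based, hence insensitive to modest
misestimation of the shrinkage level. Covariance estimation thins residual
frames (default every 4th) — ~560 frames for a 100-voxel covariance.

Cross-run distance: d_ij = ½[(1 − r(run1_i, run2_j)) + (1 − r(run1_j,
run2_i))], entries in [0, 2], diagonal meaningful. Zero-variance patterns
yield NaN entries that are excluded from contrasts with a warning.
Contrasts are dissimilar-mean minus similar-mean over hypothesis element
sets (including the diagonal), with optional exclusion of same-stimulus or
same-stimulus-set elements as controls. For structure contrasts the
collapsed 4-condition (GLM2a-style) RDM is the default readout because A/B
identity cannot be aligned across stimulus sets; the 8-condition variant is
available.

Group inference sign-flips per-subject contrast maps (flips shared across
voxels within a permutation): p = (1 + #{permuted means ≥ observed}) /
(1 + n_perm), one-tailed, with exact 2^S enumeration available for S ≤ 16.
FWE correction thresholds the map at p < 0.001, scores each suprathreshold
cluster (face connectivity by default) by its mass — the sum of the group
t statistic over member voxels — and compares observed masses to the null
distribution of the per-permutation maximum mass. Cluster forming defaults
to the parametric one-tailed Student-t quantile for the forming threshold:
it is equivalent to the stated p-threshold under the voxelwise t reference
and, unlike a permutation-p forming rule, remains attainable when n_perm <
1/threshold (a permutation-p forming mode is provided and agrees at high
n_perm). ROI tests average the searchlight RDMs across the ROI per subject
before contrasting, then run a one-tailed t-test. Leave-one-out reruns the
cluster pipeline once per held-out subject.

Small-cohort caveat: with S subjects there are only 2^S flip patterns, so
FWE-corrected p values are bounded below by roughly 2^{−S}; cohorts of
fewer than ~6 subjects cannot reach p < 0.05. With very small dof the mass
statistic can also be dominated by single voxels with freakishly small
sample variance; the permutation null keeps this valid but localization
summaries at S ≤ 3 should use cluster extent.

## Synthetic BOLD phantom

The phantom plants known representational geometry in a 20³ voxel grid
(2 mm isotropic affine for file export) with a 16³ central analysis mask
and four disjoint 150-voxel regions in the mask corners, pairwise separated
by at least 6 voxels — a 100-voxel searchlight centred at a mask corner
reaches ~(3·8·100/4π)^(1/3) ≈ 5.8 voxels, so smaller gaps would leak one
region's signal into searchlights centred in another.

Per subject, prototype patterns are drawn once per region (standard normal
over region voxels): the *structure* region keys its stimulus-onset
patterns by relational structure, the *stimulus* region by visual identity
(stimulus set × stimulus), the *PE* region keys its correctness-PE
parametric patterns by structure, and the *null* region carries no signal.
BOLD is the event design built from the subject's actual simulated trial
timings times these coefficients plus white Gaussian noise (σ = 1 by
default; an AR(1) toggle exists but the permutation statistics assume no
noise family, so white noise is the default). Defaults — effect size 1.0,
noise 1.0, 12 subjects — were chosen once to make the phantom a clear
wiring-validation instrument: it verifies that each planted geometry is
recovered by its matching contrast and by no other (the double
dissociation), not that the pipeline is powered at any particular empirical
effect size.

What passing phantom tests do *not* show about real data: the phantom has
no physiological or motion-locked noise, no spatial noise correlations
beyond what the GLM residuals induce, no inter-subject anatomical
variability (all subjects share one grid), and its effects are exactly
region-bounded. Power and FWE numbers on the phantom therefore translate to
real acquisitions only qualitatively.

## Pipeline

A single `RunConfig` (YAML round-trip, unknown keys rejected) seeds every
stage through deterministically derived child seeds; rerunning a config
reproduces every artifact bit for bit. Defaults mirror the task and
analysis conventions (switch probability 0.15, bounds [0,1]/[−1,1]/[0,8],
k = 100, n_perm = 10000, cluster-forming p = 0.001, HRF delay 6 s). The
test and calibration suites run reduced problem sizes chosen for desk-scale
iteration: 500-permutation / 500-cohort calibrations of the sign-flip and
cluster-mass machinery on 6³ grids, a 20-subject behavioral cohort for the
cross-validation pattern, and a 12-subject phantom cohort for end-to-end
detection.

## Known limitations

- Surface-based (geodesic) searchlights are replaced throughout by the
  volumetric k-nearest-neighbour variant; cortical-surface machinery is out
  of scope.
- No autocorrelation modeling in the GLM; with the phantom's white noise
  OLS is exact, and the group statistics are permutation-based.
- The optimizer is local multi-start rather than global; the recovery suite
  checks it against a coarse grid-search oracle.
- Hierarchical/Bayesian parameter estimation and lapse-rate selector
  variants are not implemented.
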