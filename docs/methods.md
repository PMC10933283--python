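# Methods

`threatdecode` implements a distributed-decoding analysis of conditioned
threat versus safety: from (optionally simulated) BOLD runs, through
trial-block GLM activation estimates, to multivariate decoders, their
interpretation, and region-community structure. This note records the
models, the parameters that matter, and the design choices made where more
than one reasonable implementation exists.

## The experimental design being modeled

The two-day paradigm has three phases of 32 trials each. Day 1: threat
conditioning (two CS+ cues paired with a mild shock at a 62.5%
reinforcement rate — 5 of 8 trials per cue — and one CS− never paired),
then extinction learning (one CS+ and the CS−, no shock). Day 2: extinction
memory recall (extinguished CS+E, unextinguished CS+U, CS−, no shock).
Every trial shows a context image for 3 s, then the CS for 6 s; a
reinforced trial ends with a 0.5 s shock co-terminating with the CS;
inter-trial intervals are uniform on [12, 18] s (mean 15 s). Trial order is
pseudorandom with at most three consecutive trials of one CS category.

Each phase is analyzed in trial-blocks (TB) of 8 trials — 4 per CS type in
a given contrast — and each trial-block is decoded separately: 4
conditioning blocks, 4 extinction blocks, and recall blocks 1–2 for both
CS+E-vs-CS− and CS+U-vs-CS− (12 contrasts). The two conditioning CS+ cues
are pooled into one CS+ condition per block by default (the block
arithmetic — 32 trials, 8 per block, 4 per CS type — requires it); an
unpooled mode is available. The 16 recall CS− trials are modeled as two
blocks of 8, each shared by the CS+E and CS+U contrast of the same block
index; the published description does not pin this down, and sharing is the
only arrangement that keeps one CS− map per recall block.

Seven trial-blocks are "robust" (significant in discovery and both
validation cohorts): conditioning TB1–4, extinction TB1, and recall TB1 for
both CS+ types. They score the extended-circuit voxel selection and the
community assignment.

## Trial-block GLM

Per run, each (trial-block × CS) cell gets one regressor: a 6 s boxcar at
its CS onsets convolved with the canonical double-gamma HRF (response gamma
peaking at 6 s, undershoot at 16 s, ratio 1/6; sampled on a 16× oversampled
grid). Shock events get their own 0.5 s regressor so CS betas are
shock-adjusted. Nuisance terms: the 6 motion parameters, a discrete-cosine
high-pass basis with a 128 s cutoff, Legendre polynomial drift up to order
2 (the order-0 term is the intercept), and one-hot spike regressors for
volumes whose Power framewise displacement (head radius 50 mm) exceeds
0.9 mm. Under ordinary least squares a one-hot spike regressor is exactly
equivalent to deleting the volume, and the test suite verifies this against
a row-deletion oracle; after AR(1) prewhitening the equivalence is only
approximate because the whitening transform mixes neighboring rows.

Noise is modeled AR(1) with a single coefficient per run pooled over voxels
(a per-voxel rho is the obvious alternative; pooled is cheaper and
sufficient at these noise levels): fit OLS, estimate the lag-1 residual
autocorrelation skipping pairs that touch a censored volume, prewhiten both
sides (first row scaled by sqrt(1 − rho²)), refit. Degenerate inputs are
rejected explicitly: rank-deficient designs, runs shorter than the design,
events past the end of the run.

## Decoding and forced-choice evaluation

The classifier is L2-regularized logistic regression on raw beta features
(no scaling — forced choice absorbs participant offsets):

    minimize  sum_i log(1 + exp(-y_i (w·x_i + b))) + ||w||² / (2c)

with CS+ = +1, an unpenalized intercept, and convergence at gradient
max-norm 1e−6. The inverse-regularization c is selected from 20 linearly
spaced values in [0.01, 100] (the literal reading of "equally distributed";
log-spacing is the plausible alternative) by 5-fold cross-validation inside
the training set, criterion mean forced-choice accuracy, ties resolved
toward the smaller c (stronger penalty). Outer evaluation: participants are
split into 5 unstratified folds; the whole procedure repeats 10 times with
split seeds = base seed + repeat index, and accuracies average over folds
and repeats.

Forced choice scores each held-out participant by comparing the decision
values of their CS+ and CS− maps; the higher one is called CS+; exact ties
score 0.5. The criterion is invariant to per-participant additive shifts
and to any strictly increasing transform of the decision function, which is
what makes frozen decoders transferable across sites and datasets; a
decoder is reapplied to external data only through the identical voxel
index record (enforced by a feature-space hash).

Numerics: the trainer solves the objective with L-BFGS. When features
outnumber training rows it first reparameterizes exactly through a thin SVD
of the training design (the component of w orthogonal to the row space is
purely penalized, hence zero at the optimum), and it can solve many label
assignments of one design in a single stacked call — the objective is
separable, so the joint optimum is the per-problem optimum. This is what
makes 1000-permutation tests that re-run the full CV pipeline tractable;
the stacked path is verified against per-problem fits and against an
independent solver (scikit-learn) to 1e−4.

## Interpretation: Haufe patterns and the permutation voxel null

Decoder weights are backward-model filters; the forward (encoding) pattern
is a = Cov(X)·w with Cov the sample feature covariance over all training
rows. Its voxel signs are interpretable: a_v > 0 means voxel v is more
activated under CS+. Patterns are stabilized by bootstrap over participants
(default 10 resamples) and tested voxel-wise against a within-participant
label-swap null: the pattern is re-estimated under 1000 permutations
(desk-scale analyses use 200), z = (a − mu0)/sigma0 from the null moments,
p = 2·Phi(−|z|) (the normal approximation, not empirical tail counts), and
Benjamini–Hochberg FDR at q < 0.05. Zero-variance nulls are flagged and
given p = 1. The permutation respects the paired structure (it swaps the
two maps of a participant rather than shuffling maps freely); the
covariance factor is label-free, so all permutations share one design
reduction.

## Masks, circuit exclusion, and the extended circuit

Sphere ROIs include every voxel whose center lies within the radius of the
mm center; the voxel containing the center is always included, so a radius
of 0 returns exactly that voxel. The whole-brain-minus-circuit feature set
removes threat-circuit voxels and their neighborhood within 3 voxels
Euclidean distance (Chebyshev would be the alternative reading of "radius
in voxels"). Extended-circuit selection scores each voxel by the mean of
−log p (natural log) across the 7 robust trial-blocks and keeps the top
10%, rounding the count up, ties broken toward the lower voxel index.
Feature extraction concatenates masked voxels in strictly increasing linear
index order — bit-stable across runs, and invertible through the stored
index record.

## Representational similarity and communities

For region i with v_i voxels, the weighted regional response of participant
n is Y_{n,i} = w_i·(x_{n,i,CS+} − x_{n,i,CS−})/v_i, with w_i the
full-circuit decoder's weights restricted to the region (one decoder per
scored block; per-region retraining is the alternative the wording leaves
open). Y columns are correlated across participants (Pearson) into the
region × region similarity matrix R, embedded in 2-D by classical
(Torgerson) MDS of D = 1 − R (double-centered −D²/2, top two eigenvectors
scaled by the root eigenvalues, negative eigenvalues truncated).

Community assignment needs a *preference* sign per (region, block), and a
decoder-weighted score cannot provide it: for any self-consistently trained
w, the expectation of w_i·(x+ − x−) is nonnegative for every region that
helps the classification — it measures contribution to the decision,
whichever CS the region prefers, because w_i aligns with the region's own
mean difference. The package therefore takes the preference sign from the
size-normalized mean regional activation difference (the fixed-orientation
functional whose sign the red/blue predictive-pattern maps display), and
feeds it through the step rule: all scored blocks positive → consistent
CS+; all negative → consistent CS−; any sign change or exact zero →
flexible. The weighted Y still drives R and the embedding.

## The synthetic cohort generator

Beta maps follow: value = baseline + participant effect (scalar Gaussian
map offset, SD 0.5) + gain_s·(±delta_{i,b}/2 · profile) + offset_s + iid
Gaussian noise (SD 1), sign + for CS+ maps. Within-region profiles are
unit-norm with spatially heterogeneous entries (Gaussian around a positive
mean, net orientation positive): mixed-sign patterns are what real
predictive maps look like, and a spatially uniform profile would make the
planted signal collinear with the participant-offset direction, forcing the
raw-map classifier to fight offset noise for exactly the direction carrying
the signal. Site structure is a per-site multiplicative gain and additive
offset on the signal — the minimal transform forced-choice scoring must be
robust to. Members of a coding community share a per-participant
effect-size factor (1 + 0.5·g_{n,c} in the three-community profile):
without shared within-community variability the cross-participant
correlations R are near-identity and the similarity analysis would have
nothing to find.

Coding profiles: `null` (delta ≡ 0), `uniform`, `dynamics` (full-strength
conditioning, extinction and recall effects at TB1 only — the qualitative
accuracy-vs-trial-block shape of the experiment), and `three_community`
(6 consistent-CS+, 4 consistent-CS−, 14 flexible regions, matching the
24-region extended circuit). With unit-norm profiles and per-map noise SD
sigma, the generative forced-choice ceiling for a planted difference delta
is Phi(delta/(sigma·sqrt(2))) = Phi(d/2) with d = sqrt(2)·delta/sigma.

Simulated BOLD: design × true betas + linear drift + stationary AR(1)
noise; motion is a bounded Gaussian random walk, with optional spike
volumes (1.2 mm jump) that exceed the 0.9 mm censoring threshold. What the
generator does *not* emulate: spatial autocorrelation and smoothing,
physiological noise, registration error, scanner drift nonlinearity, and
hemodynamic variability across regions. Passing tests therefore demonstrate
the statistical machinery is correct and calibrated, not that effect sizes
or accuracies transfer to real cohorts.

## Inferential statistics

Decoding significance: within-participant label-permutation test rerunning
the identical CV pipeline per permutation, one-sided p with the add-one
correction (r+1)/(n_perm+1) by default (raw exceedance counting, reported
as "p < 1/(n_perm+1)" at the floor, is available). External accuracies:
exact two-sided binomial test, minimum-likelihood definition. Group
proportion comparisons: Pearson chi-square without continuity correction
(flag available), odds ratio ad/(bc) with Wald 95% CI on the log scale, and
the Haldane–Anscombe +0.5 adjustment (flagged) when a cell is zero.
Multiple testing: Benjamini–Hochberg step-up, validated against a
brute-force oracle.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run desk-scale versions of each
analysis, chosen as the smallest sizes at which the property being checked
is identifiable: null calibration at N = 100 participants × 500 voxels with
199 permutations and 200 (script: 120) replicate cohorts, with the
chance-band assertion on the Monte-Carlo mean across replicates (a single
null cohort's CV accuracy has an SD near 7 points) and the calibration
pipeline fixed at c = 0.1 without an inner grid (type-I calibration holds
for any fixed pipeline); ceiling recovery at N = 500 × 25 voxels, where the
decoder demonstrably approaches the generative bound so a ±5-point
comparison is meaningful; dynamics at N = 120 on a 10-region atlas with 399
(script: 199) permutations per block; pattern inference at 200
permutations; GLM calibration over 500 simulated runs. The discovery-scale
analyses (n = 425, whole-brain grids) run through exactly the same code
paths via `RunConfig`.

## Known limitations

- The AR(1) coefficient is pooled across voxels; strongly heterogeneous
  autocorrelation fields would be mis-whitened.
- Voxel-wise FDR only; no cluster-extent or threshold-free inference.
- The permutation voxel test uses the normal approximation to the null, so
  very small n_perm understates tail uncertainty.
- Classical MDS can truncate negative eigenvalues for strongly
  non-Euclidean similarity structures; the embedding is a visualization
  aid, not an inferential quantity.
- The synthetic generator's realism limits are listed above; in particular,
  accuracies on synthetic cohorts are not predictions of accuracies on real
  data.
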