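# Methods

This note documents the models, estimators and numerical choices behind
`morphotype`, and what the synthetic experiments do and do not show.

## Discriminative polytope clustering

### Model and objective

Let X be the n × p matrix of covariate-adjusted, per-ROI z-scored
cortical features, split into controls (n₀) and clinical subjects (n₁).
A k-subtype solution consists of an assignment of each clinical subject
to one subtype and k linear faces (wⱼ, bⱼ). The fitted objective is the
sum over faces of the regularized squared-hinge SVM loss

  ½‖wⱼ‖² + C · [ Σ_{controls} (1/k)·max(0, 1 + (wⱼ·xᵢ + bⱼ))²
                 + Σ_{i ∈ subtype j} max(0, 1 − (wⱼ·xᵢ + bⱼ))² ],

i.e. each face separates *all* controls (down-weighted by 1/k so the
control class does not dominate any single face) from that subtype's
members only. Controls lie on the negative side of every face; the faces
form a convex polytope around the control group. Squared hinge solved in
the primal (liblinear, `dual=False`) is used because it is deterministic
(no solver randomness, so fixed seeds reproduce bit-identically) and
converges fast on the non-separable label configurations that arise
mid-optimization; it retains the max-margin contract of the model.

### Optimization

Alternating minimization: fit the k faces for the current assignment,
then reassign each clinical subject to argmaxⱼ (wⱼ·x + bⱼ) (ties to the
lowest subtype index), until assignments reach a fixed point or
`max_iterations` (default 50). An empty subtype is reseeded with the
clinical subject having the lowest maximum decision value whose removal
does not empty another subtype — the least "polytope-like" patient —
which keeps the degenerate case deterministic.

**Initialization.** Restarts are initialized by diversity-promoting
random exemplars: k clinical subjects drawn by k-means++-style D²
sampling, everyone assigned to the nearest exemplar. Purely random label
draws make both initial faces fit essentially the same clinical-vs-
control direction, and the synchronous argmax reassignment then freezes
into poor self-consistent fixed points (recovery ARI ≈ 0 even on cleanly
separated planted subtypes); spatially coherent, spread-out starts let
the first round of face fits differentiate, after which the alternation
reliably reaches the lowest-objective solution. On tiny instances
(7 clinical subjects, exhaustive enumeration of all 2⁷ assignments) the
alternating procedure with 5 restarts reaches the enumerated optimum in
20/20 random instances (asserted at ≥ 18/20 within 5%).

**Consensus.** `n_restarts` seeded restarts (default 20) accumulate a
clinical × clinical co-assignment frequency matrix; average-linkage
agglomeration on 1 − co-assignment yields k consensus groups (labels
numbered by first appearance in subject order), and the polytope is
refit once from the consensus labels. The refit model, its training
standardization parameters and the ROI list are stored so new or held-out
subjects can be assigned (`assign_new`, `ClusteringSolution.predict`).

### Preprocessing

Nuisance covariates (age, handedness by default) are removed per ROI by
ordinary least squares fit on the pooled sample — the simplest reading of
"nuisance covariates"; a control-only fit is available via
`HydraConfig.covariate_sample="control"`. Residuals are exactly
orthogonal to each covariate (pooled fit). Note that with a zero *true*
covariate effect the *fitted* slope is still O(σ/√n), so adjustment is
never literally a no-op; the tests assert orthogonality, not identity.
Features are then z-scored per ROI over all subjects: margin methods are
scale-sensitive and ROI variances differ substantially.

Defaults: C = 0.25, 20 restarts, 50 iterations, exact-fixed-point
convergence (`tolerance=0`). C matters little on standardized features
in the regime tested (recovery identical for C ∈ [0.05, 1]).

## Choosing the number of subtypes

For each k in the sweep (default 2..10; the desk-scale analyses use
2..6), clinical subjects are split into `n_folds` seeded folds (default
10). The model is refit on all controls plus the clinical subjects
outside each fold, giving 10 solutions; for each of the 45 solution
pairs, ARI, aligned Hamming distance, and Rand index are computed on the
clinical subjects common to both training sets, and means ± sd per k are
reported. `selected_k` maximizes mean ARI, ties to the smaller k
(parsimony). With exactly 2 folds the training sets share no clinical
subjects; the pair is then compared by relabeling all clinical subjects
under each fold's polytope decision rule — the same contract as
`assign_new` — so the 2-fold configuration remains well-defined.

The indices are computed from integer contingency/pair counts, so they
agree bit-exactly with brute-force pair-counting and bijection-
enumeration oracles. Hamming alignment uses Hungarian assignment on the
(padded) contingency table, which is exact for the label-bijection
minimum.

### Permutation test

The observed statistic is the mean CV ARI at the selected k. Each of
`n_permutations` iterations shuffles the clinical/control *group* labels
over all subjects (group sizes preserved — shuffling subtype labels
would be circular, since subtype labels are the procedure's output), and
recomputes the statistic with the identical procedure and identical
derived seeds (fold split and restart initializations), making observed
and permuted statistics exchangeable under the null. The p-value uses
add-one smoothing, p = (1 + #{null ≥ obs})/(1 + N), so it is never 0 and
ties count against the observed value. Desk-scale default N = 199 (99 in
the acceptance runs); the full-scale 5000 is a config value.

Calibration was verified on 50 null cohorts (no planted effect): 3/50
rejections at α = 0.05, consistent with the nominal rate (asserted
≤ 10%). Exchangeability makes this calibration independent of cohort
size or CV configuration, which is why small null cohorts (30 controls,
40 clinical, 20 ROIs, 5 folds, 1 restart) suffice.

## Group statistics

Two-sample comparisons use the Welch (unequal-variance) t-test by
default (pooled-variance behind `equal_var=True`); missing phenotype
values are dropped pairwise, and a variable with < 2 non-missing values
in either group is marked untestable and excluded from the FDR family.
The FDR family is the set of variables in one call (all ROIs of one
parameter for one contrast, or all clinical variables of one contrast);
families are never pooled across analyses. Benjamini–Hochberg is
implemented as the vectorized step-up q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j clipped
to 1 — the (p·m)/rank evaluation order is fixed so adjusted values agree
bit-exactly with an independent hand recomputation. The subtype-by-
diagnosis table uses Pearson chi-square without continuity correction
(df = 1); three-group contrasts use one-way fixed-effects ANOVA with
Tukey HSD post-hoc only when the omnibus test is significant at α.

## Convergence and membership consistency

Conjunction is plain set intersection of significant-ROI masks on a
shared atlas. Masks from a different parcellation are first projected
through a row-stochastic ROI-overlap crosswalk: a target ROI is included
iff ≥ 50% of its incoming overlap comes from masked source ROIs (the
0.5 threshold is the package's choice for reconciling incompatible
parcellations; the crosswalk itself is synthetic plumbing, since no
common space is defined for two arbitrary atlases). Network summaries
report 100·|mask ∩ network|/|network| per network — the fraction of each
network altered.

Dice membership consistency aligns two equal-k labelings on their shared
subjects by the label bijection maximizing total overlap (exhaustive for
k ≤ 4 with enumeration-order tie-break; Hungarian beyond), then reports
per-pair dice 2|A∩B|/(|A|+|B|) and the pair-size-weighted mean — equal to
matched-overlap/n, hence symmetric in the two solutions. Shared-subject
restriction handles cells that exclude dual-diagnosis subjects.

## Synthetic cohort generator

The generator emulates the study design it stands in for: 105 controls
and 148 clinical males (primary ASD with probability 99/148, dual
diagnoses at 13/148, independent of subtype by default — per-subtype mix
probabilities are available to give the chi-square stage something to
detect), 400 ROIs under a fine "functional" atlas (desk-scale analyses
use 100–150), a coarse "anatomical" atlas reached through a crosswalk,
and seven resting-state networks.

Per ROI: baseline mean ~ U(1.5, 4.5) (cortical-parameter analog; scales
are cosmetic because fitting standardizes), linear age effect on all
ROIs (default −0.005 per year over ages 20–50, the magnitude of adult
cortical thinning), a handedness effect on a random 10% of ROIs, and
Gaussian noise (σ = 0.15). Each planted subtype shifts its own randomly
drawn `affected_fraction` of ROIs (default 0.3) by
`effect_size · noise_sd`; the default pattern alternates signs across
subtypes (subtype 1 thicker, subtype 2 thinner — the inverse-alteration
pattern), and the per-subtype ROI sets overlap by chance. The default
effect size d = 1.5 is the strong-separation regime in which the
emulated design's near-ceiling CV stability is attainable; it is a
planted-truth dial for testing, not an estimate of real cortical effect
sizes (typical case-control ROI effects are far smaller).

What passing tests show: the estimator recovers planted structure of
this form — linearly separated, Gaussian, covariate-confounded subtypes —
selects the right k, and is calibrated under the null. What they do not
show: performance under non-Gaussian site effects, subtype imbalance
beyond the sampled range, nonlinear subtype boundaries, or real-data
effect sizes, where CV ARI values well below 1 (as in real cohorts) are
expected.

## Desk-scale problem sizes

The simulated experiments are sized for a single CPU: recovery runs use
80 controls / 120 clinical / 100 ROIs with k swept over 2..6, 10 folds
and 8 restarts per fold fit; calibration uses 50 null cohorts of
30/40/20 with 5 folds, 1 restart and 99 permutations; the acceptance
script runs the full 2 × 2 cell design at 105/148 subjects with 150
fine / 50 coarse ROIs, k ∈ 2..5 and 99 permutations. These are the
package's own desk-scale study conditions; the full-scale configuration
(400 ROIs, k ≤ 10, 5000 permutations, 20 restarts) is reachable through
the same config objects.

## Known limitations

- The alternating fit guarantees only a fixed point, not the global
  optimum; consensus over restarts mitigates but does not eliminate
  local-optimum risk, especially for weak effects or large k.
- Faces are linear; no kernels.
- Covariate adjustment is linear and homogeneous across groups.
- The crosswalk-based cross-atlas projection is a synthetic stand-in for
  true anatomical overlap between parcellations.
- `run_pipeline` executes the permutation test only in the reference
  cell by default (`permute_all_cells=False`), mirroring a primary-
  analysis design.
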