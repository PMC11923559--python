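# Methods

`cpmnet` implements connectome-based predictive modeling (CPM) of a
scalar phenotype — a regional tau SUVR, an amyloid-β DVR, or a cognitive
score — from resting-state functional connectivity, together with a
synthetic-cohort generator that makes every stage of the pipeline
verifiable in the absence of shareable imaging data.

## The model

Each subject contributes a functional connectome: a symmetric n×n
Pearson correlation matrix between parcel time courses (default
parcellation: 449 nodes — 400 cortical parcels over the 17 canonical
resting-state networks, 17 cerebellar parcels, 32 subcortical parcels —
giving n(n−1)/2 = 100,576 unique edges).

On a training set, every edge's FC values are correlated with the
phenotype across subjects by two-sided Spearman rank correlation; edges
with p below a threshold (default 0.01) form a **positive mask** (ρ > 0)
and a **negative mask** (ρ < 0), which are modeled separately end to
end. A subject's **network strength** for a tail is the plain sum of FC
values over that mask (no Fisher z-transform anywhere), and phenotype is
regressed on strength by univariate OLS. Held-out subjects are predicted
as intercept + slope × strength.

Accuracy is estimated by k-fold cross-validation (k = 8 for a 32-subject
cohort → folds of 4; k = 7 for 35 → folds of 5): selection and fit use
the training folds only, predictions are pooled over all subjects within
an iteration, and the pooled Pearson r between actual and predicted
values is the iteration's accuracy. Fold assignment is random, so the
procedure is repeated (default 50 iterations) and the per-iteration r
values are averaged arithmetically (not Fisher-z averaged). Significance
comes from a permutation null: the phenotype is shuffled across
subjects, one fresh k-fold run is executed per shuffle (default 1000),
and p = (1 + #{null r ≥ observed mean r}) / (1 + n_perm). The add-one
rule keeps p strictly in (0, 1].

Degenerate folds (empty mask, or constant strengths in training) fall
back to predicting the training-target mean and are counted and logged;
this keeps pooled accuracy defined on unlucky folds rather than
aborting. If pooled predictions are constant, r is defined as 0.

### Interpretation maps

The reported feature network is the **consensus mask**: each edge's
selection frequency over all fold-models × iterations, binarised at a
frequency cutoff (default 0.5; the raw frequency map is always
exported — the binarisation convention is a genuine free choice). Node
**degree** counts consensus edges incident to each node (max n−1 = 448).
Degrees and edge counts are aggregated over parcellation groups: cortex
by its 17 networks; cerebellar and subcortical nodes as their own
groups. Both mean and summed degree per group are emitted, since both
conventions appear in practice. A subcortical table reports per-node
degree grouped by structure (32 rows for the default parcellation).

### Preprocessing

Per run: drop the initial dummy frames (default 4, T1 stabilisation),
censor frames with framewise displacement (FD) strictly above 0.2 mm
(error if fewer than 10 frames survive), demean each node's series,
regress the unweighted across-node mean (the global signal) out of every
node by OLS, keep residuals; runs are then concatenated along frames.
Censoring precedes demeaning/GSR so that motion spikes cannot
contaminate the run mean or the global-signal regressor — the step order
and the global-signal definition are configurable because published
descriptions typically leave them unstated. The first frame of an
fMRIPrep confounds table has undefined FD (written `n/a`); it is read as
0 and never censored.

### Group-difference t statistics

`summary_ttest` recomputes two-sample t statistics from n/mean/SD
triplets alone (pooled variance by default, Welch via flag, sign =
mean(first) − mean(second)), so published demographic tables can be
checked without subject-level data. Two zero-SD groups with equal means
define t = 0.

## The synthetic generator

The generator is a forward model chosen for testability, not a causal
claim about whether pathology drives connectivity or vice versa:

1. Phenotype first: y ~ N(mean, sd) per subject (defaults 1.3 ± 0.3,
   tau-SUVR-like); z = (y − mean)/sd.
2. Target correlation matrix: block baseline from the parcellation's
   network labels (within-network `baseline_correlation`, default 0.1;
   zero across networks), plus `effect_size` × z on each planted
   positive edge and −`effect_size` × z on each planted negative edge.
3. The target is projected to the nearest correlation matrix (Higham
   alternating projection, tolerance 1e-8, max 100 sweeps, eigenvalue
   floor at the end). If the projection must move a planted edge by
   more than 0.05 the spec is signalled infeasible.
4. Frames are zero-mean multivariate normal draws from the target
   (default 2 runs × 120 TRs at TR = 3 s, 4 dummy frames carrying a
   decaying T1-stabilisation transient).
5. FD trace: baseline |N(0.08 mm, 0.03 mm)| clipped below 0.19 mm
   (matching typical compliant-cohort summaries), with independent
   spikes at `fd_spike_rate` of magnitude `fd_spike_magnitude_mm`
   (> 0.2 mm). Spike frames receive additive noise at 3× the signal SD,
   so censoring has a measurable benefit, not a cosmetic one.

Everything is reproducible bit-for-bit from the spec seed.

**Feasibility constraints.** Positive semidefiniteness jointly bounds
the correlation magnitudes incident to a node, so planted effects cannot
be arbitrarily large wherever planted edges share nodes. Two design
choices keep specs feasible: planted deltas saturate at |z| = 1.5
(saturation is monotone, so Spearman selection is unaffected), and the
planted-edge sampler caps each node at ~2 planted edges and draws
across-network pairs (baseline 0) when a parcellation is supplied. At
the recovery-experiment scale (64 subjects, 60 nodes, 30 edges per tail,
effect 0.3) fewer than 5% of subject targets need any projection and the
maximum observed planted-edge drift is ≈0.014, well under the 0.05
infeasibility signal.

**What the generator does not emulate:** hemodynamics and autocorrelated
BOLD noise, realistic head-motion kinematics, site/scanner effects, and
spatial geometry (the parcellation is a metadata table, not an atlas
volume). Passing recovery tests therefore demonstrates the pipeline's
statistical machinery, not performance on real fMRI.

**A GSR caveat the generator exposes:** global-signal regression
redistributes planted covariance onto edges that share a node with a
planted edge, producing correlated-but-unplanted selections (all
observed false positives in the recovery experiment touch planted
nodes). This mirrors the known real-data property that GSR reshapes
covariance structure. The selection-consistency test therefore evaluates
the edge-selection step on connectomes built without GSR; the end-to-end
recovery test keeps GSR on and scores recall and significance.

## Numerical choices

- Spearman ρ via average ranks; p-values from the t approximation with
  n−2 degrees of freedom (the same default as common statistical
  libraries), vectorised over all edges at once. An exact enumeration
  (`exact_spearman_p`, n ≤ 8) exists as a small-n reference.
- Selection is strictly sign-partitioned: a significant edge joins
  exactly one tail.
- No multiple-testing correction in edge selection — thresholded
  univariate screening is the method's defining feature; the robustness
  sweep (p thresholds 0.2 → 0.01) is the supported sensitivity check.
- Seeds: a master seed spawns per-iteration and per-permutation child
  seeds via `numpy.random.SeedSequence`, so results are reproducible and
  subject-order invariant given a fixed fold assignment.
- Null calibration runs use a single-iteration observed statistic so the
  observed and null draws are exchangeable by construction; with a
  50-iteration observed mean compared against single-run nulls the
  percentile p is only approximately uniform (slightly conservative).
- Edge vectors use canonical upper-triangle order ((i, j), i < j,
  ascending i then j, 0-based) and round-trip losslessly with the
  matrix form.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run on scaled-down cohorts
chosen so a full run finishes in minutes on one CPU: recovery at
64 subjects × 60 nodes × (2 × 200 usable frames), 30 planted edges per
tail, 10 CV iterations, 200 (tests) or 100 (script) permutations over
20 (tests) or 6 (script) generator seeds; null calibration at
30 subjects × 40 nodes over 100 (tests) or 60 (script) zero-effect
cohorts with 100 permutations each. Production-scale defaults (50
iterations, 1000 permutations, 449 nodes) remain the library defaults.

## Known limitations

- The OLS strength→phenotype map is deliberately minimal; regularised or
  nonlinear variants are out of scope.
- Leave-one-out and nested cross-validation (e.g. for threshold tuning)
  are not provided.
- The permutation scheme re-randomises folds once per shuffle rather
  than averaging 50 iterations per shuffle; this is conservative in
  compute and standard for CPM, but it is a convention, exposed as such.
- Graph metrics beyond degree (betweenness, clustering, …) are not
  computed.
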