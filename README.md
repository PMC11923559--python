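# cpmnet

Connectome-based predictive modeling (CPM) of regional brain pathology
and cognition from resting-state functional connectivity.

Given per-subject parcellated resting-state time series (with framewise
displacement traces) and one scalar phenotype per subject — a regional
tau SUVR, an amyloid-β DVR, or a cognitive score — `cpmnet` builds each
subject's functional connectome, selects phenotype-associated edges on
training subjects, summarises connectomes as positive/negative network
strengths, and cross-validates a linear prediction of the phenotype,
with permutation-based significance and network-level interpretation
maps. It is aimed at researchers relating functional connectivity to
PET or neuropsychological measures in small, deeply phenotyped cohorts,
where cross-validation discipline and motion-confound controls matter.

## The method in brief

For subject *s* with connectome edge values **x**ₛ and phenotype yₛ:

1. **Edge selection** (training set only): per edge *e*, Spearman
   ρ(x₍·ₑ₎, y) across subjects; masks M⁺ = {e : ρ > 0, p < 0.01} and
   M⁻ = {e : ρ < 0, p < 0.01}, modeled separately.
2. **Network strength**: Sₛ± = Σₑ∈M± xₛₑ.
3. **Model**: ŷₛ = β₀ + β₁ Sₛ± by ordinary least squares.
4. **Evaluation**: k-fold cross-validation (each subject tested exactly
   once), pooled Pearson r(y, ŷ) per iteration, averaged over 50
   re-randomised iterations; significance as the add-one percentile of
   the observed mean r within a 1000-shuffle permutation null.
5. **Interpretation**: consensus edge mask (selection frequency across
   fold-models, binarised at 0.5), node degree (max n−1), and
   aggregation over the 17 cortical networks plus cerebellar and
   subcortical groups.

Preprocessing per run before any of this: drop dummy frames, censor
frames with FD > 0.2 mm, demean, regress out the global signal,
concatenate runs, then Pearson-correlate all node pairs (449×449 by
default: 400 cortical + 17 cerebellar + 32 subcortical parcels,
100,576 unique edges).

Because cohorts of this kind are typically not shareable, the package
includes a synthetic-cohort generator with *planted* edge–phenotype
couplings (a forward model: phenotype drawn first, target correlation
matrices conditioned on it and projected to the nearest valid
correlation matrix), so that edge recovery, prediction accuracy, null
calibration, and the benefit of motion censoring are all measurable.
See `docs/methods.md` for the full model description and design
choices.

## Worked example

Simulate a 24-subject cohort with 10 positive and 10 negative planted
edges on a 40-node parcellation, then fit and test the model:

```bash
cat > spec.toml <<'EOF'
n_subjects = 24
n_nodes = 40
frames_per_run = 124
n_positive_edges = 10
n_negative_edges = 10
effect_size = 0.3
EOF

cpmnet simulate --spec spec.toml --out cohort --seed 7
cpmnet null --data-dir cohort --out results --k 6 \
       --n-iterations 10 --n-perm 200 --seed 1
cpmnet report --results-dir results
```

which prints:

```
cpmnet run: 24 subjects, 40 nodes (780 edges), fold sizes [4, 4, 4, 4, 4, 4]
  positive network: mean r = 0.989, p = 0.004975 (200 permutations)
  negative network: mean r = 0.981, p = 0.004975 (200 permutations)
```

`mean r` is the cross-validated accuracy (Pearson correlation between
actual and out-of-fold predicted phenotype, averaged over 10 fold
re-randomisations); p = 1/201 means the observed accuracy beat all 200
null accuracies obtained by shuffling the phenotype — at this strong
planted effect the model recovers the coupling essentially perfectly.
`results/` also contains per-subject predictions, per-iteration r,
consensus edge lists, node-degree and network-pair tables, and a
provenance record sufficient to regenerate every file.

The same analyses are available as a library
(`cpmnet.run_pipeline`, `cpmnet.repeat_cv`, `cpmnet.permutation_null`,
…), and further subcommands cover connectome export (`connectome`),
interpretation maps from an edge list (`maps`), and the edge-selection
threshold robustness sweep (`sweep`).

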