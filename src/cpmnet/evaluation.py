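"""Cross-validated accuracy, permutation nulls, motion controls, summary t-tests.

Accuracy is estimated by k-fold cross-validation: within one iteration,
edge selection and the OLS fit happen on the training folds only, the
held-out fold is predicted, predictions are pooled across folds, and the
Pearson correlation between actual and predicted values is the pooled
accuracy r — computed once per tail. Because fold assignment is random,
the procedure is repeated (default 50 iterations) and the per-iteration
r values are averaged arithmetically.

Significance comes from a permutation null: the phenotype is shuffled
across subjects, one fresh k-fold run is executed per shuffle (default
1000), and the p-value is the add-one percentile of the observed mean r
in the null distribution, so p is always in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cpm import (
    NEGATIVE,
    POSITIVE,
    TAILS,
    EdgeMask,
    edge_select,
    fit_cpm,
    predict_cpm_many,
)
from .exceptions import DegenerateInputError

logger = logging.getLogger(__name__)

DEFAULT_N_ITERATIONS = 50
DEFAULT_N_PERM = 1000


@dataclass
class FoldAssignment:
    """Balanced random partition of subjects into k folds."""

    k: int
    mapping: dict  # subject id -> fold index
    seed: int | None = None

    def fold_indices(self, subject_ids) -> list[np.ndarray]:
        """Positional indices of each fold, in the order of ``subject_ids``."""
        folds = [[] for _ in range(self.k)]
        for pos, sid in enumerate(subject_ids):
            folds[self.mapping[sid]].append(pos)
        return [np.array(f, dtype=np.intp) for f in folds]


@dataclass
class KFoldResult:
    """One iteration: pooled per-subject predictions and accuracy per tail."""

    actual: np.ndarray
    predictions: dict  # tail -> per-subject predicted values
    r: dict  # tail -> pooled Pearson r
    fold_masks: dict  # tail -> list of EdgeMask, one per fold
    n_degenerate: int = 0


@dataclass
class PredictionResult:
    """Iteration-averaged cross-validated accuracy."""

    actual: np.ndarray
    mean_predictions: dict  # tail -> per-subject mean prediction over iterations
    per_iteration_r: dict  # tail -> array of pooled r, one per iteration
    mean_r: dict  # tail -> arithmetic mean over iterations
    n_iterations: int
    fold_masks: dict  # tail -> all fold masks across iterations
    n_degenerate: int = 0


@dataclass
class NullDistribution:
    """Permutation null of the pooled accuracy, with add-one percentile p."""

    null_r: dict  # tail -> array of length n_perm
    observed: dict  # tail -> observed mean r
    p_value: dict  # tail -> (1 + #{null >= observed}) / (1 + n_perm)
    n_perm: int


@dataclass
class GroupSummary:
    """n / mean / SD triplet for one measure in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def assign_folds(subject_ids, k: int, seed) -> FoldAssignment:
    """Uniformly random balanced partition; fold sizes differ by at most 1."""
    subject_ids = list(subject_ids)
    n = len(subject_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = [n // k + (1 if f < n % k else 0) for f in range(k)]
    mapping, start = {}, 0
    for f, size in enumerate(sizes):
        for pos in order[start:start + size]:
            mapping[subject_ids[pos]] = f
        start += size
    return FoldAssignment(k=k, mapping=mapping,
                          seed=seed if isinstance(seed, int) else None)


def _pooled_r(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson r of pooled predictions; 0.0 when either side is constant."""
    if np.ptp(actual) == 0 or np.ptp(predicted) == 0:
        return 0.0
    return float(np.corrcoef(actual, predicted)[0, 1])


def run_kfold(edges: np.ndarray, targets: np.ndarray, k: int,
              p_threshold: float = 0.01, seed=None,
              folds: FoldAssignment | None = None,
              subject_ids=None, collect_masks: bool = True) -> KFoldResult:
    """One cross-validation iteration over a subjects×edges matrix.

    Training and test sets never share a subject; each subject is
    predicted exactly once. Degenerate folds (empty mask or constant
    strengths) fall back to the training-mean prediction and are counted.
    """
    edges = np.asarray(edges, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n = edges.shape[0]
    if targets.shape[0] != n:
        raise ValueError("edges and targets disagree on subject count")
    if subject_ids is None:
        subject_ids = list(range(n))
    if folds is None:
        folds = assign_folds(subject_ids, k, seed)
    idx = folds.fold_indices(subject_ids)

    preds = {t: np.full(n, np.nan) for t in TAILS}
    masks = {t: [] for t in TAILS}
    n_degenerate = 0
    for test in idx:
        train = np.setdiff1d(np.arange(n), test, assume_unique=True)
        pos_mask, neg_mask = edge_select(edges[train], targets[train], p_threshold)
        for mask in (pos_mask, neg_mask):
            model = fit_cpm(edges[train], targets[train], mask)
            if model.degenerate:
                n_degenerate += 1
                logger.debug("degenerate %s-tail fold (|mask|=%d)",
                             mask.tail, len(mask))
            preds[mask.tail][test] = predict_cpm_many(model, edges[test])
            if collect_masks:
                masks[mask.tail].append(mask)

    r = {t: _pooled_r(targets, preds[t]) for t in TAILS}
    return KFoldResult(actual=targets, predictions=preds, r=r,
                       fold_masks=masks, n_degenerate=n_degenerate)


def repeat_cv(edges: np.ndarray, targets: np.ndarray, k: int,
              p_threshold: float = 0.01,
              n_iterations: int = DEFAULT_N_ITERATIONS,
              master_seed: int = 0,
              collect_masks: bool = True) -> PredictionResult:
    """Re-randomised k-fold runs; accuracies averaged arithmetically per tail."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(n_iterations)
    per_r = {t: np.empty(n_iterations) for t in TAILS}
    pred_sum = {t: np.zeros(len(targets)) for t in TAILS}
    all_masks = {t: [] for t in TAILS}
    n_degenerate = 0
    for it, child in enumerate(children):
        res = run_kfold(edges, targets, k, p_threshold,
                        seed=np.random.default_rng(child),
                        collect_masks=collect_masks)
        for t in TAILS:
            per_r[t][it] = res.r[t]
            pred_sum[t] += res.predictions[t]
            all_masks[t].extend(res.fold_masks[t])
        n_degenerate += res.n_degenerate
    return PredictionResult(
        actual=np.asarray(targets, dtype=float),
        mean_predictions={t: pred_sum[t] / n_iterations for t in TAILS},
        per_iteration_r=per_r,
        mean_r={t: float(per_r[t].mean()) for t in TAILS},
        n_iterations=n_iterations,
        fold_masks=all_masks,
        n_degenerate=n_degenerate,
    )


def permutation_null(edges: np.ndarray, targets: np.ndarray, k: int,
                     observed: dict,
                     p_threshold: float = 0.01,
                     n_perm: int = DEFAULT_N_PERM,
                     master_seed: int = 0) -> NullDistribution:
    """Shuffle targets, one fresh k-fold run per shuffle, add-one percentile p."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    targets = np.asarray(targets, dtype=float)
    children = np.random.SeedSequence(master_seed, spawn_key=(1,)).spawn(n_perm)
    null_r = {t: np.empty(n_perm) for t in TAILS}
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        shuffled = rng.permutation(targets)
        res = run_kfold(edges, shuffled, k, p_threshold, seed=rng,
                        collect_masks=False)
        for t in TAILS:
            null_r[t][i] = res.r[t]
    p = {t: float((1 + np.sum(null_r[t] >= observed[t])) / (1 + n_perm))
         for t in TAILS}
    return NullDistribution(null_r=null_r, observed=dict(observed),
                            p_value=p, n_perm=n_perm)


def motion_control_run(edges: np.ndarray, mean_fd: np.ndarray, k: int,
                       p_threshold: float = 0.01,
                       n_iterations: int = DEFAULT_N_ITERATIONS,
                       n_perm: int = DEFAULT_N_PERM,
                       master_seed: int = 0) -> tuple[PredictionResult, NullDistribution]:
    """Confound-control model: identical pipeline with mean FD as the target.

    A phenotype model is only trustworthy if this motion model predicts
    worse and stays non-significant.
    """
    result = repeat_cv(edges, mean_fd, k, p_threshold, n_iterations,
                       master_seed, collect_masks=False)
    null = permutation_null(edges, mean_fd, k, result.mean_r, p_threshold,
                            n_perm, master_seed)
    return result, null


def summary_ttest(a: GroupSummary, b: GroupSummary,
                  welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t from n/mean/SD triplets only; sign = mean(a) − mean(b).

    Pooled variance by default (Welch via flag); two-sided p with
    df = n_a + n_b − 2 (Welch–Satterthwaite under ``welch``). Two
    zero-SD groups with equal means give t = 0.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            df = a.n + b.n - 2
            return 0.0, float(df), 1.0
        raise DegenerateInputError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                      equal_var=not welch)
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        df = a.n + b.n - 2
    return float(t), float(df), float(p)
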