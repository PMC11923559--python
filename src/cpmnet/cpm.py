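"""The CPM core: edge selection, network strength, OLS fit, prediction.

Connectome-based predictive modeling summarises each subject's
connectome as the sum of functional-connectivity values over a mask of
phenotype-associated edges ("network strength") and regresses the
phenotype on that scalar. Edges are selected on training subjects only,
by two-sided Spearman rank correlation between each edge's FC values and
the phenotype across subjects at a significance threshold (default
p < 0.01), split by sign into a positive-tail and a negative-tail mask
which are modelled separately end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError

POSITIVE = "positive"
NEGATIVE = "negative"
TAILS = (POSITIVE, NEGATIVE)

DEFAULT_P_THRESHOLD = 0.01


@dataclass
class EdgeMask:
    """One tail's selected edge-vector positions for a given training set."""

    tail: str
    indices: np.ndarray  # sorted edge-vector positions
    p_threshold: float = DEFAULT_P_THRESHOLD
    rho: np.ndarray | None = None  # Spearman rho at each selected edge

    def __post_init__(self):
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}")
        self.indices = np.asarray(self.indices, dtype=np.intp)

    def __len__(self) -> int:
        return self.indices.size

    @property
    def is_empty(self) -> bool:
        return self.indices.size == 0


@dataclass
class CPMModel:
    """Univariate OLS mapping network strength → phenotype for one tail."""

    tail: str
    mask: EdgeMask
    slope: float
    intercept: float
    fallback_mean: float
    degenerate: bool = False
    training_strengths: np.ndarray | None = None
    training_targets: np.ndarray | None = None


def spearman_edges(train_edges: np.ndarray,
                   train_targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p for every edge column at once.

    ``train_edges`` is subjects×edges. Average ranks handle ties; the
    p-value uses the t approximation with n−2 degrees of freedom. Edges
    with zero variance across subjects get rho=0, p=1.
    """
    x = np.asarray(train_edges, dtype=float)
    y = np.asarray(train_targets, dtype=float)
    n = x.shape[0]
    rx = stats.rankdata(x, axis=0)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    sx = np.sqrt((rx * rx).sum(axis=0))
    sy = np.sqrt(float(ry @ ry))
    constant = sx == 0
    sx[constant] = 1.0
    rho = (ry @ rx) / (sx * sy)
    np.clip(rho, -1.0, 1.0, out=rho)
    rho[constant] = 0.0
    # t approximation; |rho|=1 maps to p=0
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    p[constant] = 1.0
    return rho, p


def exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for one Spearman correlation.

    Enumerates all n! target orderings; only sensible for n ≤ 8. Serves
    as a small-n reference for the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 8:
        raise ValueError("exact enumeration is limited to n <= 8")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(stats.spearmanr(x, y).statistic)
    count = total = 0
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        if abs(r) >= obs - 1e-12:
            count += 1
    return count / total


def edge_select(train_edges: np.ndarray, train_targets: np.ndarray,
                p_threshold: float = DEFAULT_P_THRESHOLD) -> tuple[EdgeMask, EdgeMask]:
    """Select positive- and negative-tail edge masks on training subjects.

    Returns ``(positive, negative)`` masks; an edge can enter at most one
    tail because the split is by the sign of rho.
    """
    x = np.asarray(train_edges, dtype=float)
    y = np.asarray(train_targets, dtype=float)
    if x.ndim != 2:
        raise ValueError("train_edges must be subjects×edges")
    if x.shape[0] != y.shape[0]:
        raise ValueError("subject counts differ between edges and targets")
    if x.shape[0] < 4:
        raise DegenerateInputError("edge selection needs at least 4 training subjects")
    if np.ptp(y) == 0:
        raise DegenerateInputError("training targets are all equal")
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must lie in (0, 1)")

    rho, p = spearman_edges(x, y)
    sig = p < p_threshold
    pos = np.flatnonzero(sig & (rho > 0))
    neg = np.flatnonzero(sig & (rho < 0))
    return (
        EdgeMask(POSITIVE, pos, p_threshold, rho=rho[pos]),
        EdgeMask(NEGATIVE, neg, p_threshold, rho=rho[neg]),
    )


def network_strength(edge_vector: np.ndarray, mask: EdgeMask) -> float:
    """Sum of the subject's FC values over the mask's edges (0 if empty)."""
    if mask.is_empty:
        return 0.0
    v = np.asarray(edge_vector, dtype=float)
    if mask.indices.max() >= v.size:
        raise ValueError("mask index out of range for this edge vector")
    return float(v[mask.indices].sum())


def strengths(edge_matrix: np.ndarray, mask: EdgeMask) -> np.ndarray:
    """Network strength for every row of a subjects×edges matrix."""
    x = np.asarray(edge_matrix, dtype=float)
    if mask.is_empty:
        return np.zeros(x.shape[0])
    return x[:, mask.indices].sum(axis=1)


def fit_cpm(train_edges: np.ndarray, train_targets: np.ndarray,
            mask: EdgeMask) -> CPMModel:
    """OLS of target on network strength; degenerate masks fall back to the mean."""
    y = np.asarray(train_targets, dtype=float)
    fallback = float(y.mean())
    s = strengths(train_edges, mask)
    if mask.is_empty or np.ptp(s) == 0:
        return CPMModel(mask.tail, mask, slope=0.0, intercept=fallback,
                        fallback_mean=fallback, degenerate=True,
                        training_strengths=s, training_targets=y)
    res = stats.linregress(s, y)
    return CPMModel(mask.tail, mask, slope=float(res.slope),
                    intercept=float(res.intercept), fallback_mean=fallback,
                    training_strengths=s, training_targets=y)


def predict_cpm(model: CPMModel, edge_vector: np.ndarray) -> float:
    """Predicted phenotype for one subject's edge vector."""
    if model.degenerate:
        return model.fallback_mean
    return model.intercept + model.slope * network_strength(edge_vector, model.mask)


def predict_cpm_many(model: CPMModel, edge_matrix: np.ndarray) -> np.ndarray:
    """Vectorised :func:`predict_cpm` over a subjects×edges matrix."""
    n = np.asarray(edge_matrix).shape[0]
    if model.degenerate:
        return np.full(n, model.fallback_mean)
    return model.intercept + model.slope * strengths(edge_matrix, model.mask)
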