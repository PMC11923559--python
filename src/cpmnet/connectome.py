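"""Build per-subject functional connectomes from parcellated time series.

The processing chain per run is: drop dummy frames → censor high-motion
frames (framewise displacement above threshold) → demean each node's
series → regress the global signal (unweighted mean across nodes) out of
every node → keep residuals. Runs are then concatenated along frames and
the connectome is the pairwise Pearson correlation matrix of the
concatenated series.

Censoring precedes demeaning/global-signal regression so that motion
spikes cannot contaminate the run mean or the global-signal regressor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InsufficientDataError, ZeroVarianceError

logger = logging.getLogger(__name__)

#: Default framewise-displacement censoring threshold (mm).
DEFAULT_FD_THRESHOLD_MM = 0.2

#: Minimum number of frames that must survive censoring in a run.
MIN_FRAMES_PER_RUN = 10


@dataclass
class SubjectTimeSeries:
    """Per-run parcellated signals plus framewise-displacement traces.

    ``runs[r]`` is a frames×nodes array; ``fd[r]`` its per-frame FD in mm
    (first frame 0 by convention — FD is undefined for the first volume).
    """

    subject_id: str
    runs: list[np.ndarray]
    fd: list[np.ndarray]
    tr_seconds: float = 3.0
    node_labels: list[str] | None = None

    def __post_init__(self):
        if not self.runs:
            raise DegenerateInputError("subject has no runs")
        n_nodes = self.runs[0].shape[1]
        for r, (sig, fd) in enumerate(zip(self.runs, self.fd)):
            if sig.shape[0] != fd.shape[0]:
                raise ValueError(
                    f"run {r}: {sig.shape[0]} frames but {fd.shape[0]} FD values"
                )
            if sig.shape[1] != n_nodes:
                raise ValueError("node count differs across runs")

    @property
    def n_nodes(self) -> int:
        return self.runs[0].shape[1]

    def mean_fd(self, drop_dummy: int = 0,
                fd_threshold_mm: float | None = None) -> float:
        """Mean FD over retained frames of all runs.

        With ``fd_threshold_mm`` set, censored frames are excluded, i.e.
        the mean is over the frames that actually enter the connectome.
        """
        chunks = []
        for fd in self.fd:
            fd = fd[drop_dummy:]
            if fd_threshold_mm is not None:
                fd = fd[fd <= fd_threshold_mm]
            chunks.append(fd)
        allfd = np.concatenate(chunks)
        if allfd.size == 0:
            raise InsufficientDataError(f"{self.subject_id}: no retained frames")
        return float(allfd.mean())


@dataclass
class Connectome:
    """Symmetric unit-diagonal correlation matrix for one subject."""

    subject_id: str
    matrix: np.ndarray
    n_frames_used: int = 0

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def censor_frames(run_signal: np.ndarray, fd_vector: np.ndarray,
                  fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM) -> np.ndarray:
    """Remove frames with FD strictly above threshold, preserving order."""
    if fd_threshold_mm <= 0:
        raise ValueError("fd_threshold_mm must be positive")
    run_signal = np.asarray(run_signal, dtype=float)
    fd_vector = np.asarray(fd_vector, dtype=float)
    if run_signal.shape[0] != fd_vector.shape[0]:
        raise ValueError("signal and FD lengths differ")
    keep = fd_vector <= fd_threshold_mm
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("censored %d of %d frames (FD > %.3g mm)",
                    n_removed, keep.size, fd_threshold_mm)
    kept = run_signal[keep]
    if kept.shape[0] < MIN_FRAMES_PER_RUN:
        raise InsufficientDataError(
            f"only {kept.shape[0]} frames survive censoring (need ≥{MIN_FRAMES_PER_RUN})"
        )
    return kept


def _regress_global_signal(signal: np.ndarray) -> np.ndarray:
    """Residualise every node on the frame-wise mean across nodes (OLS)."""
    g = signal.mean(axis=1)
    gg = float(g @ g)
    if gg == 0.0:
        return signal.copy()
    beta = (g @ signal) / gg
    return signal - np.outer(g, beta)


def preprocess_and_concatenate(subject: SubjectTimeSeries,
                               drop_dummy: int = 4,
                               fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
                               gsr: bool = True) -> np.ndarray:
    """Per run: drop dummies, censor, demean, global-signal regression; concatenate.

    Returns the concatenated frames×nodes residual table.
    """
    if subject.n_nodes < 2:
        raise DegenerateInputError(
            "global-signal regression on a single node would zero the data"
        )
    pieces = []
    for sig, fd in zip(subject.runs, subject.fd):
        if drop_dummy >= sig.shape[0]:
            raise InsufficientDataError("dummy drop removes the whole run")
        sig, fd = sig[drop_dummy:], fd[drop_dummy:]
        sig = censor_frames(sig, fd, fd_threshold_mm)
        sig = sig - sig.mean(axis=0)
        if gsr:
            sig = _regress_global_signal(sig)
        pieces.append(sig)
    return np.concatenate(pieces, axis=0)


def compute_connectome(concatenated_signal: np.ndarray,
                       subject_id: str = "") -> Connectome:
    """Pairwise Pearson correlation matrix with unit diagonal."""
    x = np.asarray(concatenated_signal, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise InsufficientDataError("need a frames×nodes table with ≥3 frames")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ZeroVarianceError(dead)
    m = np.corrcoef(x, rowvar=False)
    np.clip(m, -1.0, 1.0, out=m)
    np.fill_diagonal(m, 1.0)
    return Connectome(subject_id=subject_id, matrix=m, n_frames_used=x.shape[0])


def build_connectome(subject: SubjectTimeSeries,
                     drop_dummy: int = 4,
                     fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
                     gsr: bool = True) -> Connectome:
    """Full chain from raw runs to one connectome."""
    sig = preprocess_and_concatenate(subject, drop_dummy, fd_threshold_mm, gsr)
    return compute_connectome(sig, subject_id=subject.subject_id)


# ---------------------------------------------------------------------------
# Edge-vector flattening: canonical upper-triangle order, (i,j) with i<j,
# ascending i then j, 0-based — the order produced by np.triu_indices.

def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) node-index arrays for each edge-vector position."""
    return np.triu_indices(n_nodes, k=1)


def edge_index(i: int, j: int, n_nodes: int) -> int:
    """Edge-vector position of the pair (i, j), i < j."""
    if not (0 <= i < j < n_nodes):
        raise ValueError(f"need 0 <= i < j < n_nodes, got ({i}, {j})")
    return i * (2 * n_nodes - i - 1) // 2 + (j - i - 1)


def to_edge_vector(connectome: Connectome | np.ndarray) -> np.ndarray:
    """Flatten a symmetric matrix to its canonical upper-triangle vector."""
    m = connectome.matrix if isinstance(connectome, Connectome) else np.asarray(connectome)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    iu, ju = edge_pairs(m.shape[0])
    return m[iu, ju].copy()


def from_edge_vector(edge_vector: np.ndarray, n_nodes: int,
                     diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix from its edge vector."""
    v = np.asarray(edge_vector, dtype=float)
    if v.shape != (n_edges(n_nodes),):
        raise ValueError(
            f"edge vector length {v.size} is not n(n-1)/2 for n={n_nodes}"
        )
    m = np.full((n_nodes, n_nodes), diagonal, dtype=float)
    iu, ju = edge_pairs(n_nodes)
    m[iu, ju] = v
    m[ju, iu] = v
    return m
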