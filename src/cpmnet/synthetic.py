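"""Synthetic resting-state cohorts with planted edge–phenotype couplings.

The generator is a forward model: a scalar phenotype (e.g. a regional
tau SUVR) is drawn first, and each subject's target correlation matrix
is conditioned on it — baseline block structure from the parcellation's
network labels (within-network ``baseline_correlation``, zero across
networks) plus, on each planted edge, ``effect_size`` × the subject's
standardised phenotype (sign-flipped on negative-tail edges). The target
is projected to the nearest valid correlation matrix, frames are drawn
as zero-mean multivariate normals, and a framewise-displacement trace
with independent spikes is attached. Spike frames are corrupted with
additive noise at 3× the signal SD so that motion censoring has a
measurable benefit downstream.

Everything is reproducible bit-for-bit from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import SubjectTimeSeries, edge_index
from .cpm import NEGATIVE, POSITIVE, EdgeMask
from .exceptions import InfeasibleSpecError
from .parcellation import default_parcellation, write_parcellation

#: Maximum a planted edge may move during PSD projection before the
#: spec is declared infeasible.
MAX_PLANTED_DRIFT = 0.05

#: Planted correlations are clipped to this magnitude before projection.
CLIP_CORRELATION = 0.95

#: Additive corruption on spike frames, in units of the (unit) signal SD.
SPIKE_NOISE_SD = 3.0


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth description of a synthetic cohort.

    Defaults mirror the acquisition they emulate: two 120-TR runs at
    TR = 3 s with 4 dummy frames, a 449-node parcellation, censoring-
    relevant FD spikes above 0.2 mm, and a tau-SUVR-like phenotype
    (mean 1.3, SD 0.3).
    """

    n_subjects: int
    n_nodes: int = 449
    n_runs: int = 2
    frames_per_run: int = 120
    dummy_frames: int = 4
    tr_seconds: float = 3.0
    phenotype_mean: float = 1.3
    phenotype_sd: float = 0.3
    positive_edges: tuple[tuple[int, int], ...] = ()
    negative_edges: tuple[tuple[int, int], ...] = ()
    effect_size: float = 0.0
    baseline_correlation: float = 0.1
    fd_spike_rate: float = 0.03
    fd_spike_magnitude_mm: float = 0.5
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "positive_edges",
                           tuple(sorted(map(tuple, self.positive_edges))))
        object.__setattr__(self, "negative_edges",
                           tuple(sorted(map(tuple, self.negative_edges))))
        pos, neg = set(self.positive_edges), set(self.negative_edges)
        if pos & neg:
            raise ValueError("positive and negative planted edges overlap")
        for i, j in pos | neg:
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"planted edge ({i},{j}) needs 0 <= i < j < n_nodes")
        if not -1 < self.baseline_correlation < 1:
            raise ValueError("baseline_correlation must lie in (-1, 1)")
        if abs(self.baseline_correlation) + 2 * abs(self.effect_size) >= 1:
            raise ValueError("|baseline ± 2·effect| must stay below 1")
        if self.frames_per_run <= self.dummy_frames:
            raise ValueError("frames_per_run must exceed dummy_frames")
        if self.fd_spike_magnitude_mm <= 0.2:
            raise ValueError("fd_spike_magnitude_mm must exceed the 0.2 mm threshold")
        if not 0 <= self.fd_spike_rate < 1:
            raise ValueError("fd_spike_rate must lie in [0, 1)")
        if self.phenotype_sd <= 0:
            raise ValueError("phenotype_sd must be positive")


@dataclass
class SyntheticCohort:
    """Generated subjects, phenotypes and the spec that produced them."""

    subjects: list[SubjectTimeSeries]
    phenotypes: dict[str, float]
    truth: CohortSpec
    parcellation: pd.DataFrame

    def phenotype_vector(self) -> np.ndarray:
        return np.array([self.phenotypes[s.subject_id] for s in self.subjects])

    def target_matrix(self, subject_id: str) -> np.ndarray:
        """Recompute the subject's ground-truth correlation matrix."""
        base = baseline_matrix(self.truth, self.parcellation)
        z = (self.phenotypes[subject_id] - self.truth.phenotype_mean) \
            / self.truth.phenotype_sd
        return target_correlation_matrix(self.truth, z, base)


def random_edge_sets(n_nodes: int, n_positive: int, n_negative: int,
                     seed: int, parcellation: pd.DataFrame | None = None,
                     max_degree: int = 2) -> tuple[tuple, tuple]:
    """Sample disjoint planted positive/negative edge sets.

    Node reuse is capped at ``max_degree`` planted edges per node: PSD
    feasibility jointly constrains the correlation magnitudes incident to
    a node, so unconstrained sampling produces hub nodes whose planted
    deltas cannot all be realised. When a parcellation is given, only
    across-network pairs (baseline correlation 0) are eligible, leaving
    the full delta budget to the planted effect.
    """
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_nodes, k=1)
    if parcellation is not None:
        nets = parcellation["network"].to_numpy()
        eligible = np.flatnonzero(nets[iu] != nets[ju])
    else:
        eligible = np.arange(iu.size)
    need = n_positive + n_negative
    order = rng.permutation(eligible)
    degree = np.zeros(n_nodes, dtype=int)
    pairs, taken = [], set()
    cap = max_degree
    while len(pairs) < need and cap <= max_degree + 2:
        for c in order:
            if c in taken:
                continue
            i, j = int(iu[c]), int(ju[c])
            if degree[i] >= cap or degree[j] >= cap:
                continue
            degree[i] += 1
            degree[j] += 1
            pairs.append((i, j))
            taken.add(c)
            if len(pairs) == need:
                break
        cap += 1  # greedy saturation can strand a few slots; relax gently
    if len(pairs) < need:
        raise ValueError(
            f"cannot place {need} planted edges on {n_nodes} nodes "
            f"with max_degree<={cap - 1}")
    return tuple(pairs[:n_positive]), tuple(pairs[n_positive:])


def nearest_correlation(a: np.ndarray, tol: float = 1e-8,
                        max_sweeps: int = 100) -> np.ndarray:
    """Nearest correlation matrix by Higham's alternating projection.

    Alternates projection onto the PSD cone with projection onto the
    unit-diagonal affine set, with Dykstra's correction, until the sweep
    change falls below ``tol``. A final eigenvalue floor plus diagonal
    renormalisation guarantees the result is strictly usable by a
    Cholesky factorisation.
    """
    y = np.asarray(a, dtype=float).copy()
    correction = np.zeros_like(y)
    for _ in range(max_sweeps):
        r = y - correction
        w, v = np.linalg.eigh(r)
        x = (v * np.maximum(w, 0.0)) @ v.T
        correction = x - r
        y_prev = y
        y = x.copy()
        np.fill_diagonal(y, 1.0)
        if np.abs(y - y_prev).max() < tol:
            break
    w, v = np.linalg.eigh(y)
    if w[0] < 1e-10:
        w = np.maximum(w, 1e-8)
        y = (v * w) @ v.T
        d = np.sqrt(np.diag(y))
        y = y / np.outer(d, d)
    y = (y + y.T) / 2
    np.fill_diagonal(y, 1.0)
    return y


def baseline_matrix(spec: CohortSpec, parcellation: pd.DataFrame) -> np.ndarray:
    """Block correlation structure from network labels."""
    nets = parcellation["network"].to_numpy()
    same = nets[:, None] == nets[None, :]
    base = np.where(same, spec.baseline_correlation, 0.0)
    np.fill_diagonal(base, 1.0)
    return base


#: Planted effects saturate at ±1.5 phenotype SD. Correlation magnitudes
#: incident to one node are jointly constrained by positive
#: semidefiniteness, so unbounded per-edge deltas are infeasible whenever
#: planted edges share nodes; saturation is monotone, so rank-based edge
#: selection is unaffected.
Z_SATURATION = 1.5


def target_correlation_matrix(spec: CohortSpec, z: float,
                              base: np.ndarray) -> np.ndarray:
    """One subject's target matrix: baseline plus planted-edge deltas, PSD-projected.

    Raises :class:`InfeasibleSpecError` if the projection has to move any
    planted edge by more than :data:`MAX_PLANTED_DRIFT`.
    """
    z = float(np.clip(z, -Z_SATURATION, Z_SATURATION))
    c = base.copy()
    for sign, edges in ((1.0, spec.positive_edges), (-1.0, spec.negative_edges)):
        for i, j in edges:
            v = np.clip(base[i, j] + sign * spec.effect_size * z,
                        -CLIP_CORRELATION, CLIP_CORRELATION)
            c[i, j] = c[j, i] = v
    eigmin = np.linalg.eigvalsh(c)[0]
    if eigmin < 1e-8:
        projected = nearest_correlation(c)
        for i, j in spec.positive_edges + spec.negative_edges:
            if abs(projected[i, j] - c[i, j]) > MAX_PLANTED_DRIFT:
                raise InfeasibleSpecError(
                    f"PSD projection moves planted edge ({i},{j}) by "
                    f"{abs(projected[i, j] - c[i, j]):.3f} > {MAX_PLANTED_DRIFT}"
                )
        c = (projected + projected.T) / 2
        np.fill_diagonal(c, 1.0)
    return c


def _fd_trace(rng: np.random.Generator, n_frames: int, spec: CohortSpec) -> np.ndarray:
    """Baseline FD below the censoring threshold plus independent spikes."""
    fd = np.abs(rng.normal(0.08, 0.03, n_frames))
    np.clip(fd, 0.005, 0.19, out=fd)
    spikes = rng.random(n_frames) < spec.fd_spike_rate
    fd[spikes] = spec.fd_spike_magnitude_mm
    fd[0] = 0.0  # FD undefined for the first volume
    return fd


def generate_cohort(spec: CohortSpec,
                    parcellation: pd.DataFrame | None = None) -> SyntheticCohort:
    """Generate a full cohort from a spec; deterministic given ``spec.seed``."""
    if parcellation is None:
        parcellation = default_parcellation(spec.n_nodes)
    if len(parcellation) != spec.n_nodes:
        raise ValueError("parcellation size does not match spec.n_nodes")
    rng = np.random.default_rng(spec.seed)
    labels = parcellation["label"].tolist()
    base = baseline_matrix(spec, parcellation)

    y = rng.normal(spec.phenotype_mean, spec.phenotype_sd, spec.n_subjects)
    z = (y - spec.phenotype_mean) / spec.phenotype_sd

    width = max(2, len(str(spec.n_subjects)))
    subjects, phenotypes = [], {}
    for s in range(spec.n_subjects):
        target = target_correlation_matrix(spec, float(z[s]), base)
        chol = np.linalg.cholesky(target + 1e-9 * np.eye(spec.n_nodes))
        runs, fds = [], []
        for _ in range(spec.n_runs):
            sig = rng.standard_normal((spec.frames_per_run, spec.n_nodes)) @ chol.T
            # T1-stabilisation transient on the dummy frames
            drift = 8.0 * 0.5 ** np.arange(spec.dummy_frames)
            sig[: spec.dummy_frames] += drift[:, None]
            fd = _fd_trace(rng, spec.frames_per_run, spec)
            spikes = np.flatnonzero(fd > 0.2)
            if spikes.size:
                sig[spikes] += rng.normal(
                    0.0, SPIKE_NOISE_SD, (spikes.size, spec.n_nodes))
            runs.append(sig)
            fds.append(fd)
        sid = f"sub-{s + 1:0{width}d}"
        subjects.append(SubjectTimeSeries(sid, runs, fds,
                                          tr_seconds=spec.tr_seconds,
                                          node_labels=labels))
        phenotypes[sid] = float(y[s])

    return SyntheticCohort(subjects, phenotypes, spec, parcellation)


def truth_mask(spec: CohortSpec,
               n_nodes: int | None = None) -> tuple[EdgeMask, EdgeMask]:
    """Planted edges in canonical edge-vector indexing (the recovery gold standard)."""
    n = spec.n_nodes if n_nodes is None else n_nodes
    pos = sorted(edge_index(i, j, n) for i, j in spec.positive_edges)
    neg = sorted(edge_index(i, j, n) for i, j in spec.negative_edges)
    return (EdgeMask(POSITIVE, np.array(pos, dtype=np.intp)),
            EdgeMask(NEGATIVE, np.array(neg, dtype=np.intp)))


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write the on-disk layout consumed by the pipeline readers.

    ``<out>/parcellation.csv``, ``<out>/phenotypes.csv`` and, per
    subject, ``<out>/<sid>/run-<r>_timeseries.tsv`` (header = node
    labels) plus ``run-<r>_confounds.tsv`` with a
    ``framewise_displacement`` column in the fMRIPrep dialect (first
    frame written as ``n/a``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_parcellation(cohort.parcellation, out / "parcellation.csv")
    pd.DataFrame(
        {"subject_id": list(cohort.phenotypes),
         "value": list(cohort.phenotypes.values())}
    ).to_csv(out / "phenotypes.csv", index=False)
    for subj in cohort.subjects:
        sdir = out / subj.subject_id
        sdir.mkdir(exist_ok=True)
        for r, (sig, fd) in enumerate(zip(subj.runs, subj.fd), start=1):
            pd.DataFrame(sig, columns=subj.node_labels).to_csv(
                sdir / f"run-{r}_timeseries.tsv", sep="\t", index=False,
                float_format="%.6f")
            fd_col = np.concatenate(([np.nan], fd[1:]))
            pd.DataFrame({"framewise_displacement": fd_col}).to_csv(
                sdir / f"run-{r}_confounds.tsv", sep="\t", index=False,
                na_rep="n/a", float_format="%.6f")
    return out
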