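"""End-to-end orchestration: config, dataset IO, pipeline runs, sweeps.

A run goes: load cohort (time-series directory layout or precomputed
connectomes) → optional subgroup filter → connectome per subject →
repeated k-fold CPM → permutation null → consensus masks, degree and
network aggregation → artifacts on disk plus a provenance record that
suffices to regenerate every output.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome import (
    SubjectTimeSeries,
    build_connectome,
    n_edges,
    to_edge_vector,
)
from .cpm import TAILS
from .evaluation import (
    NullDistribution,
    PredictionResult,
    assign_folds,
    permutation_null,
    repeat_cv,
)
from .exceptions import DegenerateInputError
from .maps import (
    aggregate_networks,
    consensus_edge_table,
    consensus_mask,
    node_degree,
    subcortical_summary,
)
from .parcellation import read_parcellation

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    data_dir: str
    out_dir: str
    phenotype_csv: str | None = None  # default: <data_dir>/phenotypes.csv
    parcellation_csv: str | None = None  # default: <data_dir>/parcellation.csv
    subgroup: list[str] | None = None  # subject-id allowlist
    fd_threshold_mm: float = 0.2
    dummy_frames: int = 4
    gsr: bool = True
    p_threshold: float = 0.01
    k: int = 8
    n_iterations: int = 50
    n_perm: int = 1000
    frequency_cutoff: float = 0.5
    master_seed: int = 0

    def __post_init__(self):
        if self.fd_threshold_mm <= 0 or not (0 < self.p_threshold < 1):
            raise ValueError("thresholds must be positive (p in (0,1))")
        if self.k < 2:
            raise ValueError("k must be >= 2")

    @classmethod
    def from_toml(cls, path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def load_subject_dir(sdir: Path, subject_id: str,
                     tr_seconds: float = 3.0) -> SubjectTimeSeries:
    """Read one subject's run TSVs and fMRIPrep-dialect confounds TSVs."""
    runs, fds, labels = [], [], None
    ts_files = sorted(sdir.glob("run-*_timeseries.tsv"))
    if not ts_files:
        raise FileNotFoundError(f"no run-*_timeseries.tsv under {sdir}")
    for ts in ts_files:
        conf = ts.with_name(ts.name.replace("_timeseries", "_confounds"))
        sig = pd.read_csv(ts, sep="\t")
        labels = list(sig.columns)
        fd = pd.read_csv(conf, sep="\t", na_values=["n/a", "NA"])
        # first frame's FD is undefined in the fMRIPrep dialect; never censored
        fd = fd["framewise_displacement"].fillna(0.0).to_numpy(dtype=float)
        runs.append(sig.to_numpy(dtype=float))
        fds.append(fd)
    return SubjectTimeSeries(subject_id, runs, fds, tr_seconds=tr_seconds,
                             node_labels=labels)


def load_cohort(data_dir, subgroup=None):
    """Read the on-disk cohort layout → (subjects, phenotype Series, parcellation).

    Subjects present in the phenotype table but lacking time-series data
    are excluded with a warning; the exclusion manifest is returned too.
    """
    data_dir = Path(data_dir)
    parcellation = read_parcellation(data_dir / "parcellation.csv")
    pheno = pd.read_csv(data_dir / "phenotypes.csv").set_index("subject_id")["value"]
    if subgroup is not None:
        pheno = pheno.loc[pheno.index.intersection(list(subgroup))]
    subjects, missing = [], []
    for sid in pheno.index:
        sdir = data_dir / str(sid)
        if not sdir.is_dir():
            missing.append(str(sid))
            continue
        subjects.append(load_subject_dir(sdir, str(sid)))
    if missing:
        logger.warning("excluded %d subject(s) without time series: %s",
                       len(missing), missing)
    pheno = pheno.loc[[s.subject_id for s in subjects]]
    return subjects, pheno, parcellation, missing


def cohort_edge_matrix(subjects, fd_threshold_mm=0.2, dummy_frames=4, gsr=True):
    """Connectome per subject → subjects×edges matrix (canonical edge order)."""
    rows = [
        to_edge_vector(build_connectome(s, drop_dummy=dummy_frames,
                                        fd_threshold_mm=fd_threshold_mm, gsr=gsr))
        for s in subjects
    ]
    return np.vstack(rows)


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute the full analysis; returns the result bundle as a dict."""
    subjects, pheno, parcellation, missing = load_cohort(
        config.data_dir, config.subgroup)
    if len(subjects) < 4:
        raise DegenerateInputError(
            f"only {len(subjects)} subjects after filtering (need >= 4)")
    n_nodes = len(parcellation)
    edges = cohort_edge_matrix(subjects, config.fd_threshold_mm,
                               config.dummy_frames, config.gsr)
    targets = pheno.to_numpy(dtype=float)
    subject_ids = list(pheno.index)

    result = repeat_cv(edges, targets, config.k, config.p_threshold,
                       config.n_iterations, config.master_seed)
    null = permutation_null(edges, targets, config.k, result.mean_r,
                            config.p_threshold, config.n_perm,
                            config.master_seed)

    consensus = {t: consensus_mask(result.fold_masks[t], n_edges(n_nodes),
                                   config.frequency_cutoff)
                 for t in TAILS}
    degrees = {t: node_degree(consensus[t].as_edge_mask(), n_nodes)
               for t in TAILS}
    networks = {t: aggregate_networks(consensus[t].as_edge_mask(), parcellation)
                for t in TAILS}
    subcort = {t: subcortical_summary(degrees[t], parcellation) for t in TAILS}

    folds_example = assign_folds(subject_ids, config.k, config.master_seed)
    fold_sizes = sorted(
        np.bincount(list(folds_example.mapping.values())).tolist(), reverse=True)

    bundle = {
        "subjects": subject_ids,
        "excluded": missing,
        "edges": edges,
        "targets": targets,
        "result": result,
        "null": null,
        "consensus": consensus,
        "degrees": degrees,
        "networks": networks,
        "subcortical": subcort,
        "provenance": {
            "software": f"cpmnet {__version__}",
            "config": asdict(config),
            "n_subjects": len(subject_ids),
            "n_nodes": n_nodes,
            "n_edges": n_edges(n_nodes),
            "fold_sizes": fold_sizes,
            "excluded_subjects": missing,
        },
    }
    if write:
        write_bundle(bundle, Path(config.out_dir), parcellation)
    return bundle


def write_bundle(bundle: dict, out: Path, parcellation: pd.DataFrame) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result: PredictionResult = bundle["result"]
    null: NullDistribution = bundle["null"]

    pd.DataFrame({
        "subject_id": bundle["subjects"],
        "actual": result.actual,
        "predicted_positive": result.mean_predictions["positive"],
        "predicted_negative": result.mean_predictions["negative"],
    }).to_csv(out / "predictions.csv", index=False)

    pd.DataFrame({
        "iteration": np.arange(result.n_iterations),
        "r_positive": result.per_iteration_r["positive"],
        "r_negative": result.per_iteration_r["negative"],
    }).to_csv(out / "iteration_r.csv", index=False)

    with open(out / "results.json", "w") as fh:
        json.dump({
            "mean_r": result.mean_r,
            "p_value": null.p_value,
            "n_iterations": result.n_iterations,
            "n_perm": null.n_perm,
            "n_degenerate_folds": result.n_degenerate,
        }, fh, indent=2)

    for t in TAILS:
        consensus_edge_table(bundle["consensus"][t], parcellation,
                             include_all=True).to_csv(
            out / f"consensus_{t}.csv", index=False)
        pd.DataFrame({
            "node_id": parcellation["node_id"],
            "label": parcellation["label"],
            "degree": bundle["degrees"][t],
        }).to_csv(out / f"degree_{t}.csv", index=False)
        pair, deg_table = bundle["networks"][t]
        pair.to_csv(out / f"network_pairs_{t}.csv")
        deg_table.to_csv(out / f"network_degree_{t}.csv", index=False)
        bundle["subcortical"][t].to_csv(out / f"subcortical_{t}.csv", index=False)

    with open(out / "provenance.json", "w") as fh:
        json.dump(bundle["provenance"], fh, indent=2)


def threshold_sweep(config: RunConfig,
                    thresholds=(0.2, 0.1, 0.05, 0.01),
                    with_null: bool = False) -> pd.DataFrame:
    """Repeat the cross-validation at several edge-selection p thresholds."""
    for thr in thresholds:
        if not 0 < thr < 1:
            raise ValueError("thresholds must lie in (0, 1)")
    subjects, pheno, _, _ = load_cohort(config.data_dir, config.subgroup)
    edges = cohort_edge_matrix(subjects, config.fd_threshold_mm,
                               config.dummy_frames, config.gsr)
    targets = pheno.to_numpy(dtype=float)
    rows = []
    for thr in thresholds:
        res = repeat_cv(edges, targets, config.k, thr, config.n_iterations,
                        config.master_seed, collect_masks=False)
        pvals = {t: np.nan for t in TAILS}
        if with_null:
            null = permutation_null(edges, targets, config.k, res.mean_r,
                                    thr, config.n_perm, config.master_seed)
            pvals = null.p_value
        for t in TAILS:
            rows.append({"p_threshold": thr, "tail": t,
                         "mean_r": res.mean_r[t], "p_value": pvals[t]})
    return pd.DataFrame(rows)
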