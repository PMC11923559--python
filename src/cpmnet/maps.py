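"""Interpret fitted CPM models: consensus masks, node degree, network maps.

The mask that gets reported is not any single fold's mask but the
consensus across all fold-models and iterations: each edge's selection
frequency is computed and binarised at a cutoff (default 0.5). Node
degree counts consensus edges incident to each node (maximum
n_nodes − 1, i.e. 448 for the default parcellation), and degrees/edges
are aggregated over the parcellation's network groups — cortex by its
17 networks, with cerebellar and subcortical nodes in their own groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import edge_pairs
from .cpm import EdgeMask


@dataclass
class ConsensusMask:
    """Per-edge selection frequency over fold-models, plus its binarisation."""

    tail: str
    frequencies: np.ndarray  # length n_edges, values in [0, 1]
    indices: np.ndarray  # edge positions with frequency >= cutoff
    frequency_cutoff: float
    n_models: int

    def as_edge_mask(self) -> EdgeMask:
        return EdgeMask(self.tail, self.indices)

    def __len__(self) -> int:
        return self.indices.size


def consensus_mask(fold_masks: list[EdgeMask], n_edges: int,
                   frequency_cutoff: float = 0.5) -> ConsensusMask:
    """Selection frequency per edge over all fold-models; binarised at cutoff."""
    if not fold_masks:
        raise ValueError("need at least one fold mask")
    tails = {m.tail for m in fold_masks}
    if len(tails) > 1:
        raise ValueError(f"mixed tails in fold masks: {sorted(tails)}")
    if not 0 < frequency_cutoff <= 1:
        raise ValueError("frequency_cutoff must lie in (0, 1]")
    counts = np.zeros(n_edges)
    for m in fold_masks:
        counts[m.indices] += 1
    freq = counts / len(fold_masks)
    return ConsensusMask(tail=tails.pop(), frequencies=freq,
                         indices=np.flatnonzero(freq >= frequency_cutoff),
                         frequency_cutoff=frequency_cutoff,
                         n_models=len(fold_masks))


def node_degree(mask: EdgeMask | np.ndarray, n_nodes: int) -> np.ndarray:
    """Count of mask edges incident to each node (Σ degree = 2·|mask|)."""
    indices = mask.indices if isinstance(mask, EdgeMask) else np.asarray(mask)
    iu, ju = edge_pairs(n_nodes)
    if indices.size and indices.max() >= iu.size:
        raise ValueError("edge index out of range for n_nodes")
    deg = np.bincount(iu[indices], minlength=n_nodes)
    deg += np.bincount(ju[indices], minlength=n_nodes)
    return deg


def group_labels(parcellation: pd.DataFrame) -> pd.Series:
    """Aggregation group per node: cortical network, else anatomical class."""
    cls = parcellation["anatomical_class"]
    labels = parcellation["network"].where(cls == "cortex")
    labels = labels.mask(cls == "cerebellum", "Cerebellum")
    labels = labels.mask(cls == "subcortex", "Subcortex")
    if labels.isna().any():
        bad = parcellation.loc[labels.isna(), "node_id"].tolist()
        raise ValueError(f"nodes without aggregation group: {bad}")
    return labels


def aggregate_networks(mask: EdgeMask | np.ndarray, parcellation: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Network-pair edge counts and per-network degree summaries.

    Returns ``(pair_counts, degree_table)``: a symmetric network×network
    matrix whose (A, B) cell counts mask edges with one endpoint in A and
    one in B (within-network edges counted once, on the diagonal), and a
    per-network table with mean and summed node degree (both are
    reported because either convention appears in practice).
    """
    n_nodes = len(parcellation)
    indices = mask.indices if isinstance(mask, EdgeMask) else np.asarray(mask)
    labels = group_labels(parcellation)
    groups = sorted(labels.unique())
    gpos = {g: i for i, g in enumerate(groups)}
    node_group = labels.map(gpos).to_numpy()

    iu, ju = edge_pairs(n_nodes)
    pair = np.zeros((len(groups), len(groups)), dtype=int)
    for e in indices:
        a, b = node_group[iu[e]], node_group[ju[e]]
        a, b = min(a, b), max(a, b)
        pair[a, b] += 1
    pair = pair + np.triu(pair, k=1).T  # symmetric; diagonal counted once
    pair_counts = pd.DataFrame(pair, index=groups, columns=groups)

    deg = node_degree(indices, n_nodes)
    degree_table = (
        pd.DataFrame({"group": labels, "degree": deg})
        .groupby("group")["degree"]
        .agg(n_nodes="size", mean_degree="mean", total_degree="sum")
        .reset_index()
    )
    return pair_counts, degree_table


def subcortical_summary(degree: np.ndarray,
                        parcellation: pd.DataFrame) -> pd.DataFrame:
    """Per-node degree restricted to subcortex, ordered by structure.

    One row per subcortical node (32 for the default parcellation);
    empty when the parcellation has no subcortical nodes.
    """
    sub = parcellation[parcellation["anatomical_class"] == "subcortex"]
    if sub.empty:
        return pd.DataFrame(columns=["structure", "node_id", "label", "degree"])
    deg = np.asarray(degree)[sub["node_id"].to_numpy()]
    return (
        pd.DataFrame({
            "structure": sub["network"].to_numpy(),
            "node_id": sub["node_id"].to_numpy(),
            "label": sub["label"].to_numpy(),
            "degree": deg,
        })
        .sort_values(["structure", "node_id"], kind="stable")
        .reset_index(drop=True)
    )


def consensus_edge_table(consensus: ConsensusMask, parcellation: pd.DataFrame,
                         include_all: bool = False) -> pd.DataFrame:
    """Edge-list view of a consensus mask (node_i, node_j, frequency, selected)."""
    n_nodes = len(parcellation)
    iu, ju = edge_pairs(n_nodes)
    if include_all:
        keep = np.flatnonzero(consensus.frequencies > 0)
    else:
        keep = consensus.indices
    selected = np.isin(keep, consensus.indices)
    labels = parcellation["label"].to_numpy()
    return pd.DataFrame({
        "node_i": iu[keep], "node_j": ju[keep],
        "label_i": labels[iu[keep]], "label_j": labels[ju[keep]],
        "tail": consensus.tail,
        "frequency": consensus.frequencies[keep],
        "selected": selected,
    })
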