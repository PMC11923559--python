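"""Node metadata tables for the 449-region whole-brain parcellation.

The default table mirrors the composition used throughout the package:
400 cortical parcels (Schaefer-style, split over the 17 canonical
resting-state networks and two hemispheres), 17 cerebellar parcels (one
per network, following the cerebellar projection of the 17-network
atlas), and 32 subcortical parcels (Tian S1-style structures).

A parcellation is an ordinary :class:`pandas.DataFrame` with columns
``node_id`` (contiguous, 0-based), ``label``, ``anatomical_class``
(``cortex`` / ``cerebellum`` / ``subcortex``), ``network`` and
``hemisphere``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError

#: The 17 canonical cortical resting-state network names.
YEO17_NETWORKS = [
    "VisCent", "VisPeri", "SomMotA", "SomMotB",
    "DorsAttnA", "DorsAttnB", "SalVentAttnA", "SalVentAttnB",
    "LimbicA", "LimbicB", "ContA", "ContB", "ContC",
    "DefaultA", "DefaultB", "DefaultC", "TempPar",
]

#: Subcortical structures (per hemisphere, anterior/posterior halves → 32 nodes).
SUBCORTICAL_STRUCTURES = [
    "Hippocampus", "Amygdala", "Thalamus-anterior", "Thalamus-posterior",
    "NucleusAccumbens", "GlobusPallidus", "Putamen", "Caudate",
]

PARCELLATION_COLUMNS = ["node_id", "label", "anatomical_class", "network", "hemisphere"]


def _split_counts(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def default_parcellation(n_nodes: int = 449) -> pd.DataFrame:
    """Build the default node-metadata table.

    For ``n_nodes=449`` this is the canonical 400 + 17 + 32 composition.
    For other sizes (used by small synthetic cohorts) the cortical /
    cerebellar / subcortical proportions are kept and the cortex is
    spread over as many of the 17 networks as the node budget allows.
    """
    if n_nodes < 3:
        raise DegenerateInputError("parcellation needs at least 3 nodes")
    if n_nodes == 449:
        n_sub, n_cer = 32, 17
    else:
        n_sub = min(32, max(1, round(n_nodes * 32 / 449)))
        n_cer = min(17, max(1, round(n_nodes * 17 / 449)))
        # keep at least 2 cortical nodes
        while n_nodes - n_sub - n_cer < 2:
            if n_sub > 1:
                n_sub -= 1
            elif n_cer > 1:
                n_cer -= 1
            else:
                n_sub = n_cer = 0
                break
    n_ctx = n_nodes - n_sub - n_cer

    rows = []
    node = 0
    n_networks = min(17, max(1, n_ctx // 4)) if n_ctx < 400 else 17
    networks = YEO17_NETWORKS[:n_networks]
    for hemi, hemi_total in zip(("LH", "RH"), _split_counts(n_ctx, 2)):
        for net, count in zip(networks, _split_counts(hemi_total, len(networks))):
            for i in range(count):
                rows.append((node, f"{hemi}_{net}_{i + 1}", "cortex", net, hemi))
                node += 1
    for i in range(n_cer):
        net = networks[i % len(networks)]
        rows.append((node, f"Cerebellum_{net}", "cerebellum", net, "BOTH"))
        node += 1
    sub_labels = [
        f"{hemi}_{struct}{suffix}"
        for hemi in ("LH", "RH")
        for struct in SUBCORTICAL_STRUCTURES
        for suffix in ("", "-2")
    ]
    for i in range(n_sub):
        label = sub_labels[i % len(sub_labels)]
        hemi, struct = label.split("_", 1)
        rows.append((node, label, "subcortex", struct.removesuffix("-2"), hemi))
        node += 1

    return pd.DataFrame(rows, columns=PARCELLATION_COLUMNS)


def validate_parcellation(table: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants; returns the table for chaining."""
    missing = set(PARCELLATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
    ids = table["node_id"].to_numpy()
    if not np.array_equal(ids, np.arange(len(table))):
        raise ValueError("node_id must be contiguous and 0-based")
    if table["network"].isna().any():
        bad = table.loc[table["network"].isna(), "node_id"].tolist()
        raise ValueError(f"nodes without network label: {bad}")
    return table


def read_parcellation(path) -> pd.DataFrame:
    return validate_parcellation(pd.read_csv(path))


def write_parcellation(table: pd.DataFrame, path) -> None:
    validate_parcellation(table).to_csv(path, index=False)
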