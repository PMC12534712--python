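"""Integration and segregation metrics on binary networks.

Global efficiency is the mean inverse shortest-path length over all
ordered node pairs (disconnected pairs contribute 0).  Nodal local
efficiency is the global efficiency of the subgraph induced by a node's
neighbors (0 for nodes with fewer than 2 neighbors); local efficiency is
the arithmetic mean of the nodal scores over all nodes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _sp

from .connectome import WeightedConnectome
from .thresholding import BinaryNetwork, DensityGrid, proportional_threshold

__all__ = [
    "shortest_path_lengths",
    "global_efficiency",
    "nodal_local_efficiency",
    "local_efficiency",
    "hemisphere_subnetwork",
    "efficiency_profiles",
]


def shortest_path_lengths(g: BinaryNetwork) -> np.ndarray:
    """All-pairs BFS distances; unreachable pairs are +inf, d_ii = 0."""
    return _adjacency_distances(g.adjacency)


def _adjacency_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    d = _sp(csr_matrix(adj.astype(np.int8)), method="D", directed=False, unweighted=True)
    np.fill_diagonal(d, 0.0)
    return d


def _efficiency_from_adj(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = _adjacency_distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(g: BinaryNetwork) -> float:
    """Mean inverse distance over all pairs; in [0, 1], 1 iff complete."""
    if g.n_nodes < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _efficiency_from_adj(g.adjacency)


def nodal_local_efficiency(g: BinaryNetwork, node: str) -> float:
    """Global efficiency of the subgraph induced by ``node``'s neighbors."""
    try:
        i = g.node_labels.index(node)
    except ValueError:
        raise ValueError(f"unknown node {node!r}") from None
    return _nodal_local_efficiency_idx(g.adjacency, i)


def _nodal_local_efficiency_idx(adj: np.ndarray, i: int) -> float:
    nbrs = np.flatnonzero(adj[i])
    if nbrs.size < 2:
        return 0.0
    sub = adj[np.ix_(nbrs, nbrs)]
    return _efficiency_from_adj(sub)


def local_efficiency(g: BinaryNetwork) -> float:
    """Unweighted mean of nodal local efficiency over all nodes."""
    if g.n_nodes < 1:
        raise ValueError("local efficiency needs at least 1 node")
    adj = g.adjacency
    return float(
        np.mean([_nodal_local_efficiency_idx(adj, i) for i in range(g.n_nodes)])
    )


def hemisphere_subnetwork(w: WeightedConnectome, side: str) -> WeightedConnectome:
    """Restrict a weighted connectome to one hemisphere's nodes."""
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    idx = [i for i, h in enumerate(w.hemisphere) if h == side]
    if len(idx) < 2:
        raise ValueError(f"hemisphere {side} has fewer than 2 nodes")
    sub = w.weights[np.ix_(idx, idx)]
    raw = (
        w.raw_pearson[np.ix_(idx, idx)] if w.raw_pearson is not None else None
    )
    return WeightedConnectome(
        node_labels=[w.node_labels[i] for i in idx],
        hemisphere=[w.hemisphere[i] for i in idx],
        weights=sub,
        modality=w.modality,
        subject_id=w.subject_id,
        raw_pearson=raw,
    )


def efficiency_profiles(
    connectomes: dict[str, WeightedConnectome],
    grid: DensityGrid,
    scopes: tuple[str, ...] = ("whole", "L", "R"),
) -> pd.DataFrame:
    """Per-subject efficiency metrics across the density grid.

    Each hemisphere scope is proportionally thresholded independently at
    every grid density (mirroring per-hemisphere network construction),
    as is the whole network.  Returns a long-format table with columns
    subject_id, modality, hemisphere, density, metric, value.
    """
    rows = []
    for sid, conn in connectomes.items():
        for scope in scopes:
            wscope = conn if scope == "whole" else hemisphere_subnetwork(conn, scope)
            for d in grid:
                net = proportional_threshold(wscope, d)
                rows.append(
                    (sid, conn.modality, scope, d, "global_efficiency",
                     global_efficiency(net))
                )
                rows.append(
                    (sid, conn.modality, scope, d, "local_efficiency",
                     local_efficiency(net))
                )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "modality", "hemisphere", "density", "metric", "value"],
    )
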