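"""Inter-layer metrics on the two-layer SC-FC multiplex.

Edge overlap quantifies how many edges two equal-node-set binary
networks share (Dice normalization, which for the equal-density layers
produced by thresholding reduces to |intersection| / k and keeps the
0-for-disjoint / 1-for-identical endpoints).  Inter-layer node
assortativity is the Pearson or Spearman correlation between a node's
degree in the SC layer and its degree in the FC layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .thresholding import BinaryNetwork

__all__ = [
    "MultiplexPair",
    "edge_overlap",
    "degree_sequence",
    "interlayer_assortativity",
    "multiplex_profiles",
]


@dataclass
class MultiplexPair:
    """SC layer + FC layer of one subject on an identical node set."""

    sc: BinaryNetwork
    fc: BinaryNetwork
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.sc.node_labels != self.fc.node_labels:
            raise ValueError("layers must share an identical node label order")
        if self.sc.density_level != self.fc.density_level:
            raise ValueError("layers must be thresholded at the same density")


def edge_overlap(a: BinaryNetwork, b: BinaryNetwork) -> float:
    """Dice edge overlap: 2|E_a & E_b| / (|E_a| + |E_b|), in [0, 1]."""
    if a.node_labels != b.node_labels:
        raise ValueError("networks must share an identical node label order")
    if a.k + b.k == 0:
        raise ValueError("edge overlap undefined for two empty networks")
    iu = np.triu_indices(a.n_nodes, 1)
    inter = int((a.adjacency[iu] & b.adjacency[iu]).sum())
    return 2.0 * inter / (a.k + b.k)


def degree_sequence(g: BinaryNetwork) -> np.ndarray:
    """Per-node degree vector (row sums of the adjacency)."""
    return g.adjacency.sum(axis=1).astype(np.int64)


def interlayer_assortativity(pair: MultiplexPair, method: str = "pearson") -> float:
    """Degree-degree correlation between the two layers, nodes paired by label.

    Returns NaN (flagged undefined) when either layer's degree sequence
    has zero variance (regular graphs); that is propagated as missing
    rather than coerced to 0.
    """
    if pair.sc.k == 0 or pair.fc.k == 0:
        raise ValueError("assortativity requires both layers to be nonempty")
    da = degree_sequence(pair.sc).astype(float)
    db = degree_sequence(pair.fc).astype(float)
    if da.std() == 0 or db.std() == 0:
        return float("nan")
    if method == "pearson":
        return float(np.corrcoef(da, db)[0, 1])
    if method == "spearman":
        return float(stats.spearmanr(da, db).statistic)
    raise ValueError(f"unknown method {method!r}")


def multiplex_profiles(pairs_by_density: dict, subject_id: str | None = None) -> pd.DataFrame:
    """Long-format interlayer metrics for one subject across densities.

    ``pairs_by_density`` maps density -> MultiplexPair.  Columns:
    subject_id, density, metric, value, defined.
    """
    rows = []
    for d, pair in sorted(pairs_by_density.items()):
        sid = subject_id if subject_id is not None else pair.subject_id
        ov = edge_overlap(pair.sc, pair.fc)
        rows.append((sid, d, "overlap", ov, True))
        for method in ("pearson", "spearman"):
            val = interlayer_assortativity(pair, method)
            rows.append((sid, d, f"assort_{method}", val, not np.isnan(val)))
    return pd.DataFrame(
        rows, columns=["subject_id", "density", "metric", "value", "defined"]
    )
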