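"""Per-subject weighted connectome construction.

Functional connectomes (FC) are built from ROI time series: Pearson
correlation, absolute value of negative correlations, then Fisher's
r-to-z transform.  Structural connectomes (SC) are built from directed
streamline-count matrices: the count for a node pair is averaged across
the two tracing directions and divided by the average size of the two
ROIs, correcting for the bias of larger regions attracting more
streamlines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeightedConnectome",
    "build_fc",
    "build_sc",
    "strength_score",
    "FISHER_CLIP",
]

# |r| is clipped just below 1 so the Fisher transform stays finite.
FISHER_CLIP = 1.0 - 1e-7

SYMMETRY_TOL = 1e-10


@dataclass
class WeightedConnectome:
    """A symmetric, nonnegative, zero-diagonal weighted network.

    Node identity is carried by ``node_labels``; ``hemisphere`` tags each
    node as left ("L") or right ("R").  ``modality`` is "SC" or "FC".
    For FC, ``raw_pearson`` optionally keeps the signed pre-Fisher
    correlation matrix (needed for connectivity-strength scoring).
    """

    node_labels: list[str]
    hemisphere: list[str]
    weights: np.ndarray
    modality: str
    subject_id: str = ""
    raw_pearson: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def validate(self) -> None:
        n = self.n_nodes
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"{n} node labels"
            )
        if len(self.hemisphere) != n:
            raise ValueError("hemisphere tags must cover every node")
        if any(h not in ("L", "R") for h in self.hemisphere):
            raise ValueError("hemisphere tags must be 'L' or 'R'")
        if self.modality not in ("SC", "FC"):
            raise ValueError(f"modality must be 'SC' or 'FC', got {self.modality!r}")
        if not np.allclose(self.weights, self.weights.T, atol=SYMMETRY_TOL, rtol=0):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    def triu_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, 1)
        return self.weights[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=self.node_labels, columns=self.node_labels
        )


def _as_matrix(ts, node_labels: Sequence[str] | None):
    if isinstance(ts, pd.DataFrame):
        labels = [str(c) for c in ts.columns]
        return ts.to_numpy(dtype=float), labels
    x = np.asarray(ts, dtype=float)
    if node_labels is None:
        node_labels = [f"n{i:03d}" for i in range(x.shape[1])]
    return x, list(node_labels)


def build_fc(
    time_series,
    hemisphere: Sequence[str] | None = None,
    node_labels: Sequence[str] | None = None,
    subject_id: str = "",
) -> WeightedConnectome:
    """Build a functional connectome from a T x N time-series table.

    Weights are ``atanh(min(|r|, 1 - 1e-7))`` where ``r`` is the Pearson
    correlation between the two ROI time series.  The signed Pearson
    matrix is retained on the result as ``raw_pearson``.
    """
    x, labels = _as_matrix(time_series, node_labels)
    t, n = x.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    sd = x.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant time series for node(s): "
            f"{', '.join(labels[i] for i in constant)}"
        )
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2.0
    w = np.arctanh(np.clip(np.abs(r), 0.0, FISHER_CLIP))
    np.fill_diagonal(w, 0.0)
    if hemisphere is None:
        hemisphere = _default_hemisphere(len(labels))
    return WeightedConnectome(
        node_labels=labels,
        hemisphere=list(hemisphere),
        weights=w,
        modality="FC",
        subject_id=subject_id,
        raw_pearson=r,
    )


def build_sc(
    count_forward,
    count_reverse,
    sizes: Mapping[str, float] | pd.Series,
    hemisphere: Sequence[str] | None = None,
    node_labels: Sequence[str] | None = None,
    subject_id: str = "",
) -> WeightedConnectome:
    """Build a structural connectome from two directed count matrices.

    ``w_ij = ((forward[i,j] + reverse[j,i]) / 2) / ((size_i + size_j) / 2)``,
    symmetrized by averaging with its transpose and with the diagonal
    zeroed.  ``sizes`` maps node label to ROI size (voxel/vertex count).
    """
    f, labels = _as_matrix(count_forward, node_labels)
    if isinstance(count_reverse, pd.DataFrame):
        if [str(c) for c in count_reverse.columns] != labels:
            raise ValueError("forward/reverse count matrices disagree on node labels")
    r, _ = _as_matrix(count_reverse, labels)
    n = len(labels)
    if f.shape != (n, n) or r.shape != (n, n):
        raise ValueError("count matrices must be square over the node labels")
    if np.any(f < 0) or np.any(r < 0):
        raise ValueError("streamline counts must be nonnegative")
    sizes = pd.Series(sizes)
    missing = [lab for lab in labels if lab not in sizes.index]
    if missing:
        raise ValueError(f"missing ROI size for node(s): {', '.join(missing)}")
    s = sizes.loc[labels].to_numpy(dtype=float)
    if np.any(s <= 0):
        raise ValueError("ROI sizes must be positive")

    avg_count = (f + r.T) / 2.0
    avg_count = (avg_count + avg_count.T) / 2.0
    denom = (s[:, None] + s[None, :]) / 2.0
    w = avg_count / denom
    np.fill_diagonal(w, 0.0)
    if hemisphere is None:
        hemisphere = _default_hemisphere(n)
    return WeightedConnectome(
        node_labels=labels,
        hemisphere=list(hemisphere),
        weights=w,
        modality="SC",
        subject_id=subject_id,
    )


def strength_score(
    connectome: WeightedConnectome,
    raw_fc: np.ndarray | None = None,
    neg_policy: str = "zero",
) -> float:
    """Connectivity strength: mean upper-triangle edge value.

    For SC this is the mean normalized streamline weight.  For FC it is
    computed on the signed Pearson matrix after removing negative
    correlations; ``neg_policy`` selects how removal is done:

    - ``"zero"`` (default): negative entries set to 0 before averaging;
    - ``"abs"``: absolute value;
    - ``"drop"``: negative entries excluded from the average.
    """
    n = connectome.n_nodes
    if n < 2:
        raise ValueError("strength undefined for fewer than 2 nodes")
    iu = np.triu_indices(n, 1)
    if connectome.modality == "SC":
        return float(connectome.weights[iu].mean())
    r = raw_fc if raw_fc is not None else connectome.raw_pearson
    if r is None:
        raise ValueError("FC strength requires the pre-Fisher Pearson matrix")
    vals = np.asarray(r, dtype=float)[iu]
    if neg_policy == "zero":
        return float(np.maximum(vals, 0.0).mean())
    if neg_policy == "abs":
        return float(np.abs(vals).mean())
    if neg_policy == "drop":
        kept = vals[vals >= 0]
        if kept.size == 0:
            warnings.warn("all correlations negative; strength set to 0")
            return 0.0
        return float(kept.mean())
    raise ValueError(f"unknown neg_policy {neg_policy!r}")


def _default_hemisphere(n: int) -> list[str]:
    half = n // 2
    return ["L"] * half + ["R"] * (n - half)
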