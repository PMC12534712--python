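"""Binarization of weighted connectomes at a graded density schedule.

Two schemes are provided:

- proportional (subject-level): keep the ``d`` fraction of strongest
  edges of one subject's weighted connectome, guaranteeing networks of
  equal density across subjects;
- consistency (group-level): rank node pairs by the coefficient of
  variation (CV) of their weight across subjects and keep the ``d``
  fraction with the lowest CV, i.e. the most consistent connections.

Both are fully deterministic: the retained edge count is round-half-up
of ``d * n(n-1)/2`` and ties are broken by a fixed lexicographic rule,
so edge sets are nested along the density grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectome import WeightedConnectome

__all__ = [
    "DensityGrid",
    "BinaryNetwork",
    "make_density_grid",
    "proportional_threshold",
    "consistency_threshold",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    # small epsilon guards against 9.499999999 style float error in d*M
    return int(math.floor(x + 0.5 + 1e-9))


@dataclass(frozen=True)
class DensityGrid:
    """Equally spaced densities in (0, 1], ascending."""

    densities: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        if d.size == 0:
            raise ValueError("empty density grid")
        if np.any(d <= 0) or np.any(d > 1):
            raise ValueError("densities must lie in (0, 1]")
        if d.size > 1:
            steps = np.diff(d)
            if np.any(steps <= 0):
                raise ValueError("densities must be strictly increasing")
            if not np.allclose(steps, steps[0], atol=1e-9, rtol=0):
                raise ValueError("densities must be equally spaced")

    def __iter__(self):
        return iter(self.densities)

    def __len__(self) -> int:
        return len(self.densities)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.densities, dtype=float)


def make_density_grid(
    start: float = 0.05, stop: float = 0.70, step: float = 0.05
) -> DensityGrid:
    """Inclusive equally graded density schedule (default: 5%..70% by 5%)."""
    if not (0 < start <= stop <= 1):
        raise ValueError("need 0 < start <= stop <= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    span = stop - start
    n_steps = round(span / step)
    if abs(n_steps * step - span) > 1e-9:
        raise ValueError(f"step {step} does not divide the span [{start}, {stop}]")
    dens = tuple(round(start + i * step, 10) for i in range(n_steps + 1))
    return DensityGrid(dens)


@dataclass
class BinaryNetwork:
    """Binarized adjacency at a stated density level."""

    node_labels: list[str]
    adjacency: np.ndarray
    density_level: float
    k: int
    hemisphere: list[str] | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.node_labels)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node labels")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-loops are not allowed")
        iu = np.triu_indices(n, 1)
        realized = int(self.adjacency[iu].sum())
        if realized != self.k:
            raise ValueError(f"edge count {realized} does not match k={self.k}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def edge_set(self) -> set[tuple[str, str]]:
        iu = np.triu_indices(self.n_nodes, 1)
        return {
            tuple(sorted((self.node_labels[i], self.node_labels[j])))
            for i, j in zip(*iu)
            if self.adjacency[i, j]
        }


def _pair_rank(labels: Sequence[str]) -> np.ndarray:
    """Rank of each upper-triangle pair under lexicographic label order."""
    iu = np.triu_indices(len(labels), 1)
    pairs = [
        tuple(sorted((labels[i], labels[j]))) for i, j in zip(*iu)
    ]
    order = sorted(range(len(pairs)), key=lambda m: pairs[m])
    rank = np.empty(len(pairs), dtype=np.int64)
    rank[order] = np.arange(len(pairs))
    return rank


def _edge_count(d: float, n: int) -> int:
    m = n * (n - 1) // 2
    k = round_half_up(d * m)
    if k <= 0:
        raise ValueError(f"density {d} retains no edges on {n} nodes")
    if k > m:
        raise ValueError(f"density {d} exceeds the {m} available node pairs")
    return k


def _mask_to_network(
    mask: np.ndarray, labels: Sequence[str], hemisphere, d: float, k: int
) -> BinaryNetwork:
    n = len(labels)
    adj = np.zeros((n, n), dtype=bool)
    iu = np.triu_indices(n, 1)
    adj[iu] = mask
    adj |= adj.T
    return BinaryNetwork(
        node_labels=list(labels),
        adjacency=adj,
        density_level=float(d),
        k=k,
        hemisphere=list(hemisphere) if hemisphere is not None else None,
    )


def proportional_threshold(w: WeightedConnectome, d: float) -> BinaryNetwork:
    """Keep the round_half_up(d * n(n-1)/2) strongest edges of one subject.

    Edges are ranked by descending weight; ties are broken by
    lexicographic node-label pair order, so the result is deterministic
    and nested across densities.
    """
    n = w.n_nodes
    k = _edge_count(d, n)
    vals = w.triu_values()
    if int((vals > 0).sum()) < k:
        warnings.warn(
            f"only {int((vals > 0).sum())} nonzero weights for k={k}; "
            "zero-weight edges admitted by the deterministic tie rule"
        )
    rank = _pair_rank(w.node_labels)
    order = np.lexsort((rank, -vals))
    mask = np.zeros(vals.size, dtype=bool)
    mask[order[:k]] = True
    return _mask_to_network(mask, w.node_labels, w.hemisphere, d, k)


def stack_cohort(cohort: Sequence[WeightedConnectome]) -> np.ndarray:
    """Stack upper-triangle weights into an (n_subjects, n_pairs) array."""
    if len(cohort) < 2:
        raise ValueError("consistency thresholding needs at least 2 subjects")
    ref = cohort[0]
    for c in cohort[1:]:
        if c.node_labels != ref.node_labels:
            raise ValueError("all subjects must share an identical node set")
        if c.modality != ref.modality:
            raise ValueError("cannot mix SC and FC in one consistency cohort")
    return np.vstack([c.triu_values() for c in cohort])


def consistency_scores(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge cross-subject mean and coefficient of variation.

    CV uses the sample (n-1) standard deviation; edges whose mean weight
    is 0 get CV = +inf so structural zeros rank last.
    """
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    cv = np.full(mu.shape, np.inf)
    nz = mu > 0
    cv[nz] = sd[nz] / mu[nz]
    return mu, cv


def consistency_mask(x: np.ndarray, k: int, rank: np.ndarray) -> np.ndarray:
    """Boolean mask of the k most consistent (lowest CV) node pairs.

    Ties on CV are broken by higher cross-subject mean, then by
    lexicographic pair order (``rank``).
    """
    mu, cv = consistency_scores(x)
    order = np.lexsort((rank, -mu, cv))
    mask = np.zeros(x.shape[1], dtype=bool)
    mask[order[:k]] = True
    return mask


def consistency_threshold(
    cohort: Sequence[WeightedConnectome], d: float
) -> BinaryNetwork:
    """Group-level network of the d fraction most consistent connections."""
    x = stack_cohort(cohort)
    ref = cohort[0]
    k = _edge_count(d, ref.n_nodes)
    rank = _pair_rank(ref.node_labels)
    mask = consistency_mask(x, k, rank)
    return _mask_to_network(mask, ref.node_labels, ref.hemisphere, d, k)
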