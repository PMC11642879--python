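"""Neighborhood graphs on the cell-state manifold.

The tangent space at a cell state is approximated by the displacements to its
k nearest neighbors, so every downstream operation is parameterized by a
:class:`NeighborGraph`.  Graphs may come from expression space, physical
(spatial) coordinates, an external weighted-nearest-neighbor computation, or
the union of two graphs.  Union graphs are ragged: per-cell neighbor counts
vary, and downstream code must not assume a fixed k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["NeighborGraph", "build_knn", "union_graph", "smooth_first_moments"]

# brute-force all-pairs search below this size keeps tie-breaking exact
_BRUTE_FORCE_MAX = 4096


@dataclass
class NeighborGraph:
    """Per-cell neighbor index and distance lists.

    ``indices[i]`` holds the 0-based positions of the neighbors of cell ``i``
    (self excluded); ``distances[i]`` the matching Euclidean distances.  For
    kNN graphs every row has the same length and distances are non-decreasing
    within a row; union graphs are ragged.
    """

    indices: List[np.ndarray]
    distances: List[np.ndarray]
    source: str = "expression"

    def __post_init__(self) -> None:
        self.indices = [np.asarray(ix, dtype=np.int64) for ix in self.indices]
        self.distances = [np.asarray(d, dtype=np.float64) for d in self.distances]
        self.validate()

    @property
    def n_cells(self) -> int:
        return len(self.indices)

    @property
    def is_ragged(self) -> bool:
        sizes = {len(ix) for ix in self.indices}
        return len(sizes) > 1

    def validate(self) -> None:
        n = self.n_cells
        if len(self.distances) != n:
            raise ValueError("indices and distances must have one row per cell")
        for i, (ix, d) in enumerate(zip(self.indices, self.distances)):
            if ix.shape != d.shape:
                raise ValueError(f"cell {i}: index/distance length mismatch")
            if ix.size and (ix.min() < 0 or ix.max() >= n):
                raise ValueError(f"cell {i}: neighbor index out of range [0, {n})")
            if np.any(ix == i):
                raise ValueError(f"cell {i}: self-loop in neighbor list")
            if len(set(ix.tolist())) != ix.size:
                raise ValueError(f"cell {i}: duplicate neighbor")
            if d.size and (not np.all(np.isfinite(d)) or d.min() < 0):
                raise ValueError(f"cell {i}: invalid distance")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Rectangular (indices, distances); raises for ragged graphs."""
        if self.is_ragged:
            raise ValueError("graph is ragged; no rectangular representation")
        return np.vstack(self.indices), np.vstack(self.distances)

    @classmethod
    def from_arrays(
        cls, indices: np.ndarray, distances: np.ndarray, source: str = "external-wnn"
    ) -> "NeighborGraph":
        indices = np.asarray(indices)
        distances = np.asarray(distances)
        return cls(list(indices), list(distances), source=source)


def build_knn(coords: np.ndarray, k: int = 30, source: str = "expression") -> NeighborGraph:
    """Euclidean k-nearest-neighbor graph, self excluded.

    Deterministic: ties in distance are broken by ascending cell index.  For
    small inputs an exact all-pairs sort is used; larger inputs go through a
    tree-based search (where exact distance ties are vanishingly unlikely).
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2:
        raise ValueError("coords must be a 2-d cells x dims array")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")

    if n <= _BRUTE_FORCE_MAX:
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        # stable sort on distances -> ties broken by ascending index
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        dist = np.sqrt(np.take_along_axis(d2, order, axis=1))
    else:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        dist_all, order_all = nn.kneighbors(coords)
        order = np.empty((n, k), dtype=np.int64)
        dist = np.empty((n, k), dtype=np.float64)
        for i in range(n):
            mask = order_all[i] != i
            order[i] = order_all[i][mask][:k]
            dist[i] = dist_all[i][mask][:k]
    return NeighborGraph(list(order), list(dist), source=source)


def union_graph(g1: NeighborGraph, g2: NeighborGraph) -> NeighborGraph:
    """Per-cell set union of two graphs (e.g. expression kNN with spatial kNN).

    Distances are carried over from the contributing graph; for neighbors
    present in both, the minimum is kept.  The result is ragged in general.
    """
    if g1.n_cells != g2.n_cells:
        raise ValueError(
            f"cell-count mismatch: {g1.n_cells} vs {g2.n_cells}"
        )
    indices: List[np.ndarray] = []
    distances: List[np.ndarray] = []
    for i in range(g1.n_cells):
        merged: dict[int, float] = {}
        for ix, d in zip(g1.indices[i], g1.distances[i]):
            merged[int(ix)] = float(d)
        for ix, d in zip(g2.indices[i], g2.distances[i]):
            j = int(ix)
            merged[j] = min(merged.get(j, np.inf), float(d))
        keys = np.array(sorted(merged), dtype=np.int64)
        indices.append(keys)
        distances.append(np.array([merged[j] for j in keys]))
    return NeighborGraph(indices, distances, source="union")


def smooth_first_moments(
    values: np.ndarray, g: NeighborGraph, include_self: bool = True
) -> np.ndarray:
    """Neighborhood average (first moment) of per-cell vectors.

    Row ``i`` of the result is the mean of ``values`` over the neighbors of
    cell ``i`` (including the cell itself when ``include_self``).  NaN entries
    are propagated via nan-aware means so masked velocity dimensions stay
    masked.  Linear in the input.
    """
    values = np.asarray(values, dtype=np.float64)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    if values.shape[0] != g.n_cells:
        raise ValueError("values row count must equal graph cell count")
    out = np.empty_like(values)
    for i in range(g.n_cells):
        rows = g.indices[i]
        if include_self:
            rows = np.concatenate([[i], rows])
        if rows.size == 0:
            out[i] = values[i]
            continue
        block = values[rows]
        finite = np.isfinite(block)
        counts = finite.sum(axis=0)
        sums = np.where(finite, block, 0.0).sum(axis=0)
        # columns NaN for every contributing cell stay NaN
        out[i] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out[:, 0] if squeeze else out
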