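"""Evaluation scores for velocity fields on the cell-state manifold.

Implements the manifold-consistent-kinetics (MacK) score, cross-boundary
correctness (CBC), per-cell velocity consistency, cell speed, and cell
context-specific kinetic rates under the splicing model

    du/dt = alpha - beta u,      ds/dt = beta u - gamma s,

with the convention beta = 1, giving alpha = u + du/dt and
gamma = (u - ds/dt) / s per cell and gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import CellPopulation
from .graph import NeighborGraph
from .tangent import TSPConfig, infer_unmeasured_velocity

__all__ = [
    "mack_score",
    "select_mack_genes",
    "BoundaryPair",
    "cbc_score",
    "velocity_consistency",
    "cell_speed",
    "KineticRates",
    "cell_specific_rates",
]


def _sign_symbol(x: np.ndarray) -> np.ndarray:
    """Three-valued sign where 0 is its own symbol (a zero velocity only
    matches a zero finite difference)."""
    return np.sign(x)


def mack_score(
    pop: CellPopulation,
    g: NeighborGraph,
    t: np.ndarray,
    genes: Optional[Sequence[int]] = None,
    vkey: str = "velocity",
) -> tuple[np.ndarray, np.ndarray]:
    """Manifold-consistent-kinetics score per cell x gene and per gene.

    For cell i and gene g the score is the fraction of neighbors j (with a
    pseudotime difference, Delta t_ij != 0) for which the sign of the local
    finite difference Delta x_ij / Delta t_ij agrees with the sign of the
    estimated velocity v_i(g).  A gene whose velocity consistently points
    along the manifold's temporal ordering scores near 1; a sign-flipped
    estimate scores near 0; noise scores near 0.5.

    Returns ``(per_cell_gene, per_gene)``; cells whose neighbors are all tied
    in t (or whose velocity is missing) are NaN and excluded from the
    per-gene mean.
    """
    t = np.asarray(t, dtype=np.float64)
    if not np.all(np.isfinite(t)):
        raise ValueError("pseudotime must be finite")
    X = pop.dense_X()
    V = pop.dense_layer(vkey)
    if genes is None:
        genes = np.arange(pop.n_features)
    genes = np.asarray(genes, dtype=np.int64)
    n = pop.n_cells
    out = np.full((n, genes.size), np.nan)
    for i in range(n):
        nbrs = g.indices[i]
        if nbrs.size == 0:
            continue
        dt = t[nbrs] - t[i]
        use = dt != 0
        if not np.any(use):
            continue
        nbrs = nbrs[use]
        dt = dt[use]
        dx = X[np.ix_(nbrs, genes)] - X[i, genes]
        # sgn(dx/dt) == sgn(dx * dt) without dividing
        fd_sign = _sign_symbol(dx * dt[:, None])
        v_sign = _sign_symbol(V[i, genes])
        valid = np.isfinite(V[i, genes])
        agree = (fd_sign == v_sign[None, :]).mean(axis=0)
        out[i] = np.where(valid, agree, np.nan)
    counts = np.isfinite(out).sum(axis=0)
    sums = np.where(np.isfinite(out), out, 0.0).sum(axis=0)
    per_gene = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out, per_gene


def select_mack_genes(scores: np.ndarray, top_n: int) -> np.ndarray:
    """Indices of the ``top_n`` genes by descending score, ties by ascending
    index."""
    scores = np.asarray(scores, dtype=np.float64)
    if top_n > scores.size:
        raise ValueError("top_n exceeds number of genes")
    order = np.lexsort((np.arange(scores.size), -scores))
    return order[:top_n]


@dataclass
class BoundaryPair:
    """Boundary cells of a source state A that touch a target state B."""

    source: object
    target: object
    boundary_cells: np.ndarray  # indices into the population, all in A


def find_boundary_cells(
    g: NeighborGraph, labels: np.ndarray, A, B
) -> BoundaryPair:
    """Cells of state A with at least one neighbor in state B."""
    labels = np.asarray(labels)
    in_a = np.flatnonzero(labels == A)
    boundary = [c for c in in_a if np.any(labels[g.indices[c]] == B)]
    return BoundaryPair(A, B, np.asarray(boundary, dtype=np.int64))


def cbc_score(
    pop: CellPopulation,
    g: NeighborGraph,
    labels: np.ndarray,
    A,
    B,
    vkey: str = "velocity",
    space: str = "expression",
    embedding: Optional[str] = None,
) -> float:
    """Cross-boundary correctness of velocities for the transition A -> B.

    Mean, over the boundary cells c of A, of the mean cosine similarity
    between v_c and the displacements to the B-neighbors of c.  Computed in
    the full expression space by default (2-d embeddings distort the
    geometry); pass ``space="embedding"`` and an ``obsm`` key to override.
    Returns NaN when no boundary cell exists.
    """
    labels = np.asarray(labels)
    if not np.any(labels == A) or not np.any(labels == B):
        raise ValueError("both categories must be populated")
    if space == "expression":
        coords = pop.dense_X()
        V = pop.dense_layer(vkey)
    elif space == "embedding":
        if embedding is None or embedding not in pop.obsm:
            raise ValueError("embedding key required for space='embedding'")
        coords = pop.obsm[embedding]
        V = pop.dense_layer(vkey)
        if V.shape[1] != coords.shape[1]:
            raise ValueError("velocity layer does not match embedding dims")
    else:
        raise ValueError(f"unknown space {space!r}")
    V = np.where(np.isfinite(V), V, 0.0)
    pair = find_boundary_cells(g, labels, A, B)
    if pair.boundary_cells.size == 0:
        import warnings

        warnings.warn(f"no boundary cells between {A!r} and {B!r}", RuntimeWarning)
        return float("nan")
    per_cell = []
    for c in pair.boundary_cells:
        nbrs = g.indices[c]
        nbrs = nbrs[labels[nbrs] == B]
        disp = coords[nbrs] - coords[c]
        v = V[c]
        vn = np.linalg.norm(v)
        dn = np.linalg.norm(disp, axis=1)
        denom = vn * dn
        cosines = np.where(denom > 0, disp @ v / np.where(denom > 0, denom, 1.0), 0.0)
        per_cell.append(cosines.mean())
    return float(np.mean(per_cell))


def velocity_consistency(
    pop: CellPopulation, g: NeighborGraph, vkey: str = "velocity"
) -> np.ndarray:
    """Per-cell mean cosine similarity between v_i and its neighbors' v_j.

    Coherent uni-directional flow scores near 1; zero vectors contribute
    cosine 0.
    """
    V = pop.dense_layer(vkey)
    V = np.where(np.isfinite(V), V, 0.0)
    norms = np.linalg.norm(V, axis=1)
    out = np.zeros(pop.n_cells)
    for i in range(pop.n_cells):
        nbrs = g.indices[i]
        if nbrs.size == 0 or norms[i] == 0:
            continue
        denom = norms[i] * norms[nbrs]
        cosines = np.where(denom > 0, V[nbrs] @ V[i] / np.where(denom > 0, denom, 1.0), 0.0)
        out[i] = cosines.mean()
    return out


def cell_speed(
    velocities: np.ndarray, feature_subset: Optional[Sequence[int]] = None
) -> np.ndarray:
    """Per-cell L2 norm of the velocity over a feature subset.

    With the subset restricted to viral genes this is the infection speed;
    over all genes it quantifies e.g. cell-cycle progression speed.
    """
    V = np.asarray(velocities, dtype=np.float64)
    if feature_subset is not None:
        V = V[:, np.asarray(feature_subset, dtype=np.int64)]
    V = np.where(np.isfinite(V), V, 0.0)
    return np.linalg.norm(V, axis=1)


@dataclass
class KineticRates:
    """Cell x gene transcription rates alpha and degradation constants gamma
    (beta = 1 convention), with a validity mask (False where s ~ 0)."""

    alpha: np.ndarray
    gamma: np.ndarray
    valid: np.ndarray


def cell_specific_rates(
    pop: CellPopulation,
    g: NeighborGraph,
    cfg: Optional[TSPConfig] = None,
    genes: Optional[Sequence[int]] = None,
    du_dt: Optional[np.ndarray] = None,
    ds_dt: Optional[np.ndarray] = None,
    eps: float = 1e-6,
    spliced_key: str = "spliced",
    unspliced_key: str = "unspliced",
    vkey: str = "velocity",
) -> KineticRates:
    """Cell context-specific kinetic rates alpha = u + du/dt and
    gamma = (u - ds/dt)/s.

    ds/dt is the (spliced) velocity layer; du/dt is inferred by transferring
    the tangent coordinates fitted on spliced space to the unspliced feature
    block, unless both derivatives are supplied directly (e.g. from a
    simulator with exact ground truth).  Entries with s < eps are masked.
    """
    if unspliced_key not in pop.layers:
        raise ValueError(f"missing layer {unspliced_key!r}")
    if spliced_key not in pop.layers:
        raise ValueError(f"missing layer {spliced_key!r}")
    u = pop.dense_layer(unspliced_key)
    s = pop.dense_layer(spliced_key)
    if genes is not None:
        genes = np.asarray(genes, dtype=np.int64)
        u, s = u[:, genes], s[:, genes]
    if ds_dt is None:
        ds_dt = pop.dense_layer(vkey)
        if genes is not None:
            ds_dt = ds_dt[:, genes]
    else:
        ds_dt = np.asarray(ds_dt, dtype=np.float64)
    if du_dt is None:
        # swap the displacement basis from spliced to unspliced space:
        # build a population whose X is [spliced | unspliced] and transfer
        n_g = s.shape[1]
        joint = CellPopulation(
            X=np.hstack([s, u]),
            layers={"velocity": np.hstack([ds_dt, np.full_like(u, np.nan)])},
        )
        du_dt = infer_unmeasured_velocity(
            joint, g, cfg,
            source_features=np.arange(n_g),
            target_features=np.arange(n_g, 2 * n_g),
        )
    else:
        du_dt = np.asarray(du_dt, dtype=np.float64)
    alpha = u + du_dt
    valid = s >= eps
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(valid, (u - ds_dt) / np.where(valid, s, 1.0), np.nan)
    return KineticRates(alpha=alpha, gamma=gamma, valid=valid)
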