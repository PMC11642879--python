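"""Tangent-space projection of velocity vectors and basis-swap transfer.

A velocity vector ``v_i`` measured at cell state ``x_i`` is re-expressed as a
weighted sum of the displacement vectors to the cell's nearest neighbors,

    v_par(x_i) = sum_{j in N(i)} phi_ij * (x_j - x_i),

which constrains it to the tangent space of the local data manifold.  The
weights ``phi_i`` are found by minimizing the tangent-space-projection loss

    L(phi_i) = a * ||v_i - sum_j phi_ij d_ij||^2
               - b * cos(phi_i, phi_i_corr)
               + lambda * ||phi_i||^2,

whose first term preserves velocity magnitude, whose second term anchors the
direction to the heuristic cosine-kernel weights ``phi_i_corr`` (cosine
similarity between ``v_i`` and each displacement, the asymptotically
direction-correct form used throughout the velocity literature), and whose
third term is an L2 bound on the weights.  Defaults a=1, b=10, lambda=1.

Because the weights are coordinates in the local displacement basis, the same
``phi_i`` transfer a velocity to any other representation of the same cells —
a low-dimensional embedding, the full gene space, or a second modality —
simply by swapping the displacement basis:

    v_par(y_i) = sum_j phi_ij * (y_j - y_i).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .core_data import CellPopulation
from .graph import NeighborGraph, smooth_first_moments

__all__ = [
    "TSPConfig",
    "ProjectionWeights",
    "LinearEmbedding",
    "displacement_basis",
    "cosine_kernel_weights",
    "fit_tsp_weights",
    "project_velocities",
    "transform_velocity",
    "infer_unmeasured_velocity",
    "adaptive_step_size",
    "velocity_to_embedding",
    "baseline_cosine_projection",
]

logger = logging.getLogger(__name__)


@dataclass
class TSPConfig:
    """Hyperparameters of the tangent-space-projection loss.

    a : weight of the squared-residual (magnitude) term.
    b : weight of the cosine (direction) term.
    lam : L2 regularization weight.
    init : starting point for the optimizer — the ridge/least-squares
        closed form (``"least-squares"``), the cosine-kernel weights
        (``"cosine"``), or ``"zeros"``.
    """

    a: float = 1.0
    b: float = 10.0
    lam: float = 1.0
    max_iter: int = 200
    tol: float = 1e-6
    init: str = "least-squares"

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.lam < 0:
            raise ValueError("a, b and lam must be non-negative")
        if self.a == 0 and self.b == 0 and self.lam == 0:
            raise ValueError("at least one of a, b, lam must be positive")
        if self.init not in ("cosine", "least-squares", "zeros"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class ProjectionWeights:
    """Per-cell tangent coordinates phi over the neighbor displacements.

    Ragged: ``weights[i]`` has one entry per neighbor of cell ``i``.
    ``corr_weights`` holds the companion cosine-kernel weights on the same
    support; ``final_loss`` / ``n_iter`` are convergence diagnostics and
    ``flagged`` marks cells that could not be fitted (no neighbors or fully
    missing velocity).
    """

    weights: List[np.ndarray]
    corr_weights: List[np.ndarray]
    final_loss: np.ndarray
    n_iter: np.ndarray
    flagged: np.ndarray
    graph: NeighborGraph

    @property
    def n_cells(self) -> int:
        return len(self.weights)


@dataclass
class LinearEmbedding:
    """Linear coordinate map: features x d loading matrix plus a center."""

    loadings: np.ndarray
    center: Optional[np.ndarray] = None
    explained_variance: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=np.float64)
        q = self.loadings
        gram = q.T @ q
        if not np.allclose(gram, np.eye(q.shape[1]), atol=1e-8):
            raise ValueError("loading columns must be orthonormal (tol 1e-8)")
        if self.center is None:
            self.center = np.zeros(q.shape[0])
        else:
            self.center = np.asarray(self.center, dtype=np.float64)

    @classmethod
    def fit_pca(cls, X: np.ndarray, n_components: int = 30) -> "LinearEmbedding":
        from sklearn.decomposition import PCA

        n_components = min(n_components, min(X.shape) - 1)
        pca = PCA(n_components=n_components, svd_solver="full")
        pca.fit(np.asarray(X, dtype=np.float64))
        return cls(
            loadings=pca.components_.T,
            center=pca.mean_,
            explained_variance=pca.explained_variance_,
        )

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.center) @ self.loadings


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def displacement_basis(
    pop: CellPopulation,
    g: NeighborGraph,
    feature_subset: Optional[Sequence[int]] = None,
) -> List[np.ndarray]:
    """Per-cell displacement vectors d_ij = x_j - x_i over a feature subset.

    Returns one (k_i x f) array per cell.  Cells with empty neighborhoods get
    an empty array (flagged downstream, never fatal).
    """
    X = pop.dense_X()
    if feature_subset is not None:
        feature_subset = np.asarray(feature_subset, dtype=np.int64)
        if feature_subset.size == 0:
            raise ValueError("feature_subset must be non-empty")
        X = X[:, feature_subset]
    return [X[g.indices[i]] - X[i] for i in range(g.n_cells)]


def cosine_kernel_weights(v_i: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    """Cosine similarity between a velocity and each neighbor displacement.

    Zero where either vector is all-zero; values in [-1, 1].
    """
    deltas = np.atleast_2d(np.asarray(deltas, dtype=np.float64))
    v_i = np.asarray(v_i, dtype=np.float64)
    if deltas.shape[0] == 0:
        return np.zeros(0)
    vnorm = np.linalg.norm(v_i)
    dnorm = np.linalg.norm(deltas, axis=1)
    denom = vnorm * dnorm
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, deltas @ v_i / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(out, -1.0, 1.0)


def _tsp_loss_grad(phi, D, v, corr, cfg: TSPConfig):
    """Value and gradient of the TSP loss at phi (D is k x f)."""
    resid = v - D.T @ phi
    loss = cfg.a * resid @ resid + cfg.lam * phi @ phi
    grad = -2.0 * cfg.a * (D @ resid) + 2.0 * cfg.lam * phi
    cnorm = np.linalg.norm(corr)
    pnorm = np.linalg.norm(phi)
    if cfg.b > 0 and cnorm > 0 and pnorm > 0:
        cos = phi @ corr / (pnorm * cnorm)
        loss -= cfg.b * cos
        grad -= cfg.b * (corr / (pnorm * cnorm) - (phi @ corr) * phi / (pnorm**3 * cnorm))
    return loss, grad


def _ridge_init(D, v, a, lam):
    """Closed-form minimizer of the quadratic (b = 0) part of the loss."""
    k = D.shape[0]
    if a == 0:
        return np.zeros(k)
    if lam == 0:
        # ordinary least squares: exact tangent projection
        return np.linalg.lstsq(D.T, v, rcond=None)[0]
    A = a * (D @ D.T) + lam * np.eye(k)
    return np.linalg.solve(A, a * (D @ v))


def fit_tsp_weights(
    v_i: np.ndarray, deltas: np.ndarray, cfg: Optional[TSPConfig] = None
) -> tuple[np.ndarray, float, int]:
    """Fit the tangent coordinates of one cell.

    Dimensions where ``v_i`` is NaN (no velocity estimate) are dropped from
    both the velocity and the displacements before fitting; the returned
    weights still apply to the full displacement basis.

    Returns ``(phi, final_loss, n_iter)``.  With b = 0 the problem is a
    ridge/least-squares system and is solved in closed form; otherwise a
    bounded quasi-Newton minimizer with analytic gradient runs from the
    closed-form initialization, and the best iterate is returned even when
    the iteration cap is hit (with a warning, never an exception).
    """
    cfg = cfg or TSPConfig()
    deltas = np.atleast_2d(np.asarray(deltas, dtype=np.float64))
    v_i = np.asarray(v_i, dtype=np.float64)
    k = deltas.shape[0]
    if k == 0:
        raise ValueError("at least one displacement vector is required")

    keep = np.isfinite(v_i)
    v = v_i[keep]
    D = deltas[:, keep]
    if v.size == 0 or not np.any(v):
        return np.zeros(k), 0.0, 0

    corr = cosine_kernel_weights(v, D)

    if cfg.b == 0:
        phi = _ridge_init(D, v, cfg.a, cfg.lam)
        loss, _ = _tsp_loss_grad(phi, D, v, corr, cfg)
        return phi, float(loss), 0

    if cfg.init == "least-squares":
        phi0 = _ridge_init(D, v, cfg.a, max(cfg.lam, 1e-12))
    elif cfg.init == "cosine":
        phi0 = corr.copy()
    else:
        phi0 = np.zeros(k)
    if not np.any(phi0):
        phi0 = corr.copy()  # cosine term undefined at exactly zero

    res = minimize(
        _tsp_loss_grad,
        phi0,
        args=(D, v, corr, cfg),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-10},
    )
    loss0, _ = _tsp_loss_grad(phi0, D, v, corr, cfg)
    phi, loss = (res.x, float(res.fun))
    if loss > loss0:  # never worse than the initialization
        phi, loss = phi0, float(loss0)
    if not res.success and res.status not in (0, 1):
        logger.debug("TSP optimizer stopped early: %s", res.message)
    if res.nit >= cfg.max_iter:
        warnings.warn("TSP optimization hit max_iter; returning best iterate",
                      RuntimeWarning, stacklevel=2)
    return phi, loss, int(res.nit)


# ---------------------------------------------------------------------------
# population-level operations
# ---------------------------------------------------------------------------

def _velocity_matrix(pop, vkey, source_features):
    V = pop.dense_layer(vkey)
    if source_features is not None:
        V = V[:, np.asarray(source_features, dtype=np.int64)]
    return V


def fit_projection_weights(
    pop: CellPopulation,
    g: NeighborGraph,
    cfg: Optional[TSPConfig] = None,
    source_features: Optional[Sequence[int]] = None,
    vkey: str = "velocity",
    smooth_velocity: bool = False,
) -> ProjectionWeights:
    """Fit tangent coordinates phi for every cell of a population.

    Each cell is an independent small optimization; results do not depend on
    the order in which cells are processed.  ``smooth_velocity`` applies
    neighborhood first-moment averaging to the velocity layer before fitting
    (the displacement basis always uses the raw states).
    """
    cfg = cfg or TSPConfig()
    V = _velocity_matrix(pop, vkey, source_features)
    if smooth_velocity:
        V = smooth_first_moments(V, g, include_self=True)
    deltas = displacement_basis(pop, g, source_features)

    n = pop.n_cells
    weights: List[np.ndarray] = []
    corr: List[np.ndarray] = []
    losses = np.zeros(n)
    iters = np.zeros(n, dtype=np.int64)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        D = deltas[i]
        if D.shape[0] == 0 or not np.any(np.isfinite(V[i])):
            weights.append(np.zeros(D.shape[0]))
            corr.append(np.zeros(D.shape[0]))
            flagged[i] = True
            continue
        keep = np.isfinite(V[i])
        phi, loss, nit = fit_tsp_weights(V[i], D, cfg)
        weights.append(phi)
        corr.append(cosine_kernel_weights(V[i][keep], D[:, keep]))
        losses[i] = loss
        iters[i] = nit
    return ProjectionWeights(weights, corr, losses, iters, flagged, g)


def transform_velocity(
    weights: ProjectionWeights, target_coords: np.ndarray, g: Optional[NeighborGraph] = None
) -> np.ndarray:
    """Re-express fitted velocities in another coordinate system.

    ``v_par(y_i) = sum_j phi_ij (y_j - y_i)`` — only the displacement basis
    changes, so the operation is exact under any linear map of coordinates
    and transfers velocities to unmeasured features or modalities.
    """
    g = g or weights.graph
    target_coords = np.atleast_2d(np.asarray(target_coords, dtype=np.float64))
    if target_coords.shape[0] != g.n_cells:
        raise ValueError("target_coords row count must equal graph cell count")
    out = np.zeros((g.n_cells, target_coords.shape[1]))
    for i in range(g.n_cells):
        phi = weights.weights[i]
        if phi.size == 0:
            continue
        d = target_coords[g.indices[i]] - target_coords[i]
        out[i] = phi @ d
    return out


def project_velocities(
    pop: CellPopulation,
    g: NeighborGraph,
    cfg: Optional[TSPConfig] = None,
    source_features: Optional[Sequence[int]] = None,
    vkey: str = "velocity",
    out_vkey: str = "velocity_graphvelo",
    smooth_velocity: bool = False,
) -> tuple[CellPopulation, ProjectionWeights]:
    """Project the velocity layer onto the data manifold's tangent space.

    Writes the refined velocities to ``pop.layers[out_vkey]`` (NaN outside
    ``source_features``) and returns the fitted :class:`ProjectionWeights`.
    Cells with no neighbors keep their input velocity and are flagged.
    """
    weights = fit_projection_weights(
        pop, g, cfg, source_features, vkey=vkey, smooth_velocity=smooth_velocity
    )
    X = pop.dense_X()
    if source_features is None:
        coords = X
        cols = np.arange(pop.n_features)
    else:
        cols = np.asarray(source_features, dtype=np.int64)
        coords = X[:, cols]
    v_par = transform_velocity(weights, coords, g)
    V_in = pop.dense_layer(vkey)
    out = np.full((pop.n_cells, pop.n_features), np.nan)
    out[:, cols] = v_par
    # cells that could not be fitted keep the raw estimate
    out[weights.flagged] = V_in[weights.flagged]
    pop.layers[out_vkey] = out
    return pop, weights


def infer_unmeasured_velocity(
    pop: CellPopulation,
    g: NeighborGraph,
    cfg: Optional[TSPConfig] = None,
    source_features: Optional[Sequence[int]] = None,
    target_features: Optional[Sequence[int]] = None,
    vkey: str = "velocity",
) -> np.ndarray:
    """Transfer velocities from measured features to any target features.

    Tangent coordinates are fitted on ``source_features`` (where velocities
    exist) and applied to the displacement basis of ``target_features`` —
    the manifold in the full space and in the measured subspace being locally
    homeomorphic, one weight vector serves both.  Restricted to the source
    features this reproduces :func:`project_velocities` exactly.
    """
    weights = fit_projection_weights(pop, g, cfg, source_features, vkey=vkey)
    X = pop.dense_X()
    if target_features is None:
        target = X
    else:
        target = X[:, np.asarray(target_features, dtype=np.int64)]
    return transform_velocity(weights, target, g)


def adaptive_step_size(
    pop: CellPopulation,
    g: NeighborGraph,
    vkey: str = "velocity",
    source_features: Optional[Sequence[int]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell extrapolation step dt_i = median_j ||d_ij|| / ||v_i||.

    Scales each cell's velocity to the local sampling density so that the
    extrapolated state x_i + v_i dt_i stays within the neighborhood.  Returns
    ``(dt, defined)`` where cells with zero speed are marked undefined.
    """
    V = _velocity_matrix(pop, vkey, source_features)
    V = np.where(np.isfinite(V), V, 0.0)
    X = pop.dense_X()
    if source_features is not None:
        X = X[:, np.asarray(source_features, dtype=np.int64)]
    speeds = np.linalg.norm(V, axis=1)
    dt = np.full(pop.n_cells, np.nan)
    for i in range(pop.n_cells):
        if speeds[i] == 0 or g.indices[i].size == 0:
            continue
        dnorm = np.linalg.norm(X[g.indices[i]] - X[i], axis=1)
        dt[i] = np.median(dnorm) / speeds[i]
    return dt, np.isfinite(dt)


def velocity_to_embedding(
    pop: CellPopulation,
    emb: LinearEmbedding,
    g: NeighborGraph,
    vkey: str = "velocity",
) -> np.ndarray:
    """Carry velocities into a linear embedding via state extrapolation.

    Each cell is propagated one adaptive step, both states are mapped through
    the loading matrix Q, and the displacement is divided by the step:
    ``v_emb = ((x + v dt) Q - x Q) / dt``.  For a linear map this equals
    ``v Q`` identically; the extrapolation form is kept because it is the
    operation that generalizes to nonlinear coordinate maps.  Cells with
    undefined dt emit a zero vector and are flagged.
    """
    X = pop.dense_X()
    V = pop.dense_layer(vkey)
    V = np.where(np.isfinite(V), V, 0.0)
    dt, defined = adaptive_step_size(pop, g, vkey=vkey)
    out = np.zeros((pop.n_cells, emb.loadings.shape[1]))
    base = emb.transform(X)
    ok = defined
    if np.any(ok):
        extrapolated = emb.transform(X[ok] + V[ok] * dt[ok, None])
        out[ok] = (extrapolated - base[ok]) / dt[ok, None]
    return out


def baseline_cosine_projection(
    pop: CellPopulation,
    g: NeighborGraph,
    vkey: str = "velocity",
    source_features: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Cosine-kernel comparator: v_i = sum_j phi_corr_ij d_ij / sum_j |phi_corr_ij|.

    The normalization discards magnitude by construction; used only as the
    benchmark baseline against the tangent-space projection.
    """
    V = _velocity_matrix(pop, vkey, source_features)
    deltas = displacement_basis(pop, g, source_features)
    out = np.zeros((pop.n_cells, deltas[0].shape[1] if deltas else 0))
    for i in range(pop.n_cells):
        D = deltas[i]
        if D.shape[0] == 0:
            continue
        keep = np.isfinite(V[i])
        if not np.any(keep) or not np.any(V[i][keep]):
            continue
        w = cosine_kernel_weights(V[i][keep], D[:, keep])
        denom = np.abs(w).sum()
        if denom == 0:
            continue
        out[i] = (w @ D) / denom
    return out
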