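"""Velocity trends along a 1-d axis: P-spline smoothing, trend clustering,
and DTW-based cross-modality decoupling detection.

Per-gene velocities are smoothed along a temporal axis (pseudotime, or the
per-cell viral RNA fraction for infection trajectories) with a generalized
additive model v_g(t) = beta0 + f(t), f a penalized cubic B-spline
(second-difference penalty on the coefficients, penalty weight chosen by
generalized cross-validation).  Each fitted trend is evaluated on a grid of
100 equally spaced points; the grids are then clustered (kNN graph + Leiden
communities) into co-regulated modules, and RNA vs chromatin trend pairs are
compared by dynamic-time-warping distance to flag genes whose transcription
and chromatin-accessibility dynamics have decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "TrendFit",
    "fit_velocity_trend",
    "cluster_trends",
    "summarize_clusters",
    "dtw_distance",
    "DecouplingReport",
    "dtw_decoupling",
]

_GCV_GRID = np.logspace(-4, 6, 21)


def _bspline_design(t: np.ndarray, t_min: float, t_max: float,
                    n_interior: int, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Open-uniform B-spline design matrix over [t_min, t_max]."""
    interior = np.linspace(t_min, t_max, n_interior + 2)[1:-1]
    knots = np.concatenate([
        np.full(degree + 1, t_min), interior, np.full(degree + 1, t_max)
    ])
    n_basis = len(knots) - degree - 1
    design = BSpline.design_matrix(np.clip(t, t_min, t_max), knots, degree).toarray()
    return design, knots


@dataclass
class TrendFit:
    """Penalized-B-spline fit of a per-gene velocity trend.

    ``grid`` holds ``n_points`` equally spaced axis values covering the
    observed range, ``predictions`` the smoothed trend there.
    """

    axis: str
    knots: np.ndarray
    degree: int
    penalty: float
    coefficients: np.ndarray
    grid: np.ndarray
    predictions: np.ndarray

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t, dtype=np.float64), self.grid[0], self.grid[-1])
        design = BSpline.design_matrix(t, self.knots, self.degree).toarray()
        return design @ self.coefficients


def fit_velocity_trend(
    t: np.ndarray,
    v_g: np.ndarray,
    n_points: int = 100,
    degree: int = 3,
    n_interior_knots: int = 10,
    penalty: Optional[float] = None,
    axis: str = "pseudotime",
) -> TrendFit:
    """Smooth one gene's velocity along a temporal axis with a P-spline.

    Solves (B'B + p D2'D2) beta = B'v, where B is the cubic B-spline design
    matrix (10 interior knots) and D2 the second-difference operator on the
    coefficients; the penalty annihilates constant and linear trends, so
    those are reproduced exactly at any penalty weight.  When ``penalty`` is
    None it is chosen by generalized cross-validation over a fixed log grid.
    Predictions are evaluated at ``n_points`` equally spaced points spanning
    the observed axis range.
    """
    t = np.asarray(t, dtype=np.float64)
    v_g = np.asarray(v_g, dtype=np.float64)
    if t.size < 20:
        raise ValueError("at least 20 cells are required to fit a trend")
    if not np.all(np.isfinite(t)):
        raise ValueError("axis values must be finite")
    t_min, t_max = float(t.min()), float(t.max())
    if t_max <= t_min:
        raise ValueError("degenerate axis: all values equal")

    B, knots = _bspline_design(t, t_min, t_max, n_interior_knots, degree)
    nb = B.shape[1]
    D2 = np.diff(np.eye(nb), n=2, axis=0)
    BtB = B.T @ B
    P = D2.T @ D2
    Btv = B.T @ v_g

    def solve(lam):
        return np.linalg.solve(BtB + lam * P, Btv)

    if penalty is None:
        best = (np.inf, _GCV_GRID[0])
        n = t.size
        for lam in _GCV_GRID:
            M = np.linalg.solve(BtB + lam * P, BtB)
            edf = np.trace(M)
            beta = np.linalg.solve(BtB + lam * P, Btv)
            rss = float(((v_g - B @ beta) ** 2).sum())
            gcv = n * rss / max(n - edf, 1e-8) ** 2
            if gcv < best[0]:
                best = (gcv, lam)
        penalty = float(best[1])
    coef = solve(penalty)
    grid = np.linspace(t_min, t_max, n_points)
    G = BSpline.design_matrix(grid, knots, degree).toarray()
    return TrendFit(axis=axis, knots=knots, degree=degree, penalty=penalty,
                    coefficients=coef, grid=grid, predictions=G @ coef)


def cluster_trends(
    trends: np.ndarray, k: int = 15, resolution: float = 0.3, seed: int = 0
) -> np.ndarray:
    """Group smoothed velocity trends into modules.

    Builds a kNN graph on Euclidean distances between the genes' trend
    vectors and partitions it with the Leiden algorithm (RB-configuration
    quality, the stated resolution).  Seeded and deterministic.
    """
    import igraph
    import leidenalg

    trends = np.atleast_2d(np.asarray(trends, dtype=np.float64))
    n_genes = trends.shape[0]
    if n_genes <= k:
        raise ValueError(f"need more than k={k} genes, got {n_genes}")
    from .graph import build_knn

    g = build_knn(trends, k=k)
    edges = {(min(i, int(j)), max(i, int(j)))
             for i in range(n_genes) for j in g.indices[i]}
    graph = igraph.Graph(n=n_genes, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=np.int64)


def summarize_clusters(
    trends: np.ndarray, labels: np.ndarray
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Pointwise mean and standard deviation of the trends in each cluster."""
    trends = np.atleast_2d(np.asarray(trends, dtype=np.float64))
    labels = np.asarray(labels)
    out = {}
    for lab in np.unique(labels):
        block = trends[labels == lab]
        out[int(lab)] = (block.mean(axis=0), block.std(axis=0))
    return out


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classic dynamic-time-warping distance between two 1-d series.

    Symmetric step pattern (match / insert / delete), no window, squared
    local cost; returns the square root of the accumulated cost along the
    optimal alignment path.  Zero iff the series are identical.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n, m = a.size, b.size
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        cost_row = (a[i - 1] - b) ** 2
        prev = acc[i - 1]
        cur = acc[i]
        for j in range(1, m + 1):
            cur[j] = cost_row[j - 1] + min(prev[j], cur[j - 1], prev[j - 1])
    return float(np.sqrt(acc[n, m]))


def _minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Scale a trend to [0, 1]; constant trends map to zeros (guard)."""
    x = np.asarray(x, dtype=np.float64)
    rng = x.max() - x.min()
    if rng <= 0:
        return np.zeros_like(x)
    return (x - x.min()) / rng


@dataclass
class DecouplingReport:
    """Genes ranked by DTW distance between modality velocity trends.

    ``order`` ranks genes by descending distance; ``elbow_rank`` is the index
    (into the ranked curve) of maximum perpendicular distance to its chord;
    genes with distance strictly greater than the elbow's are ``decoupled``.
    """

    genes: np.ndarray
    distances: np.ndarray
    order: np.ndarray
    elbow_rank: int
    cutoff: float
    decoupled: np.ndarray


def _elbow_index(sorted_desc: np.ndarray) -> int:
    """Point of maximum perpendicular distance to the chord of the ranked
    curve (axes normalized to [0, 1])."""
    y = np.asarray(sorted_desc, dtype=np.float64)
    n = y.size
    if n < 3:
        return n - 1
    x = np.linspace(0.0, 1.0, n)
    rng = y[0] - y[-1]
    yn = (y - y[-1]) / rng if rng > 0 else np.zeros_like(y)
    # distance from (x, yn) to the chord from (0, yn[0]) to (1, yn[-1])
    p0 = np.array([0.0, yn[0]])
    p1 = np.array([1.0, yn[-1]])
    d = p1 - p0
    d /= np.linalg.norm(d)
    pts = np.stack([x, yn], axis=1) - p0
    perp = np.abs(pts[:, 0] * d[1] - pts[:, 1] * d[0])
    return int(np.argmax(perp))


def dtw_decoupling(
    rna_trends: np.ndarray,
    chrom_trends: np.ndarray,
    genes: Optional[Sequence] = None,
) -> DecouplingReport:
    """Flag genes whose RNA and chromatin velocity trends have decoupled.

    Each modality's trend is min-max normalized to [0, 1] (removing the
    scale difference between modalities), the DTW distance between the pair
    is computed per gene, genes are ranked by descending distance, and the
    elbow of the ranked curve sets the cutoff: genes with distance above it
    are reported as decoupled.
    """
    rna_trends = np.atleast_2d(np.asarray(rna_trends, dtype=np.float64))
    chrom_trends = np.atleast_2d(np.asarray(chrom_trends, dtype=np.float64))
    if rna_trends.shape != chrom_trends.shape:
        raise ValueError("modality trend matrices must have matching shapes")
    n_genes = rna_trends.shape[0]
    if genes is None:
        genes = np.arange(n_genes)
    genes = np.asarray(genes)
    dists = np.array([
        dtw_distance(_minmax_normalize(rna_trends[i]),
                     _minmax_normalize(chrom_trends[i]))
        for i in range(n_genes)
    ])
    order = np.lexsort((np.arange(n_genes), -dists))
    ranked = dists[order]
    elbow = _elbow_index(ranked)
    cutoff = float(ranked[elbow])
    decoupled = genes[dists > cutoff]
    return DecouplingReport(genes=genes, distances=dists, order=order,
                            elbow_rank=elbow, cutoff=cutoff, decoupled=decoupled)
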