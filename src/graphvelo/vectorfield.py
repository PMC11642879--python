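"""Continuous vector-field reconstruction in an RKHS with Gaussian bases.

The discrete per-cell velocities (x_i, v_i) are interpolated by a smooth
field

    F(x) = sum_a Gamma(x, c_a) * coef_a,      Gamma(x, c) = exp(-w ||x-c||^2),

with centers c_a subsampled from the data and coefficients found by the
regularized least-squares problem

    min_C  sum_i ||v_i - K(x_i, C)||^2 + (lam/2) * tr(C^T G C),

where K is the data-to-center kernel matrix and G the center Gram matrix
(Tikhonov regularization in the RKHS norm).  The quadratic objective is
solved by its normal equations.  The fitted field is differentiable in
closed form, giving the Jacobian J_ij(x) = dF_i/dx_j — a local, signed
readout of how regulator j shifts the rate of change of target i — and, by
binning and integrating J_ij over the regulator's abundance, an effective
one-variable dose-response curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "VectorFieldModel",
    "fit_rkhs_vectorfield",
    "DoseResponseCurve",
    "dose_response",
]

logger = logging.getLogger(__name__)


def _kernel(X: np.ndarray, centers: np.ndarray, w: float) -> np.ndarray:
    """Gaussian kernel matrix exp(-w ||x - c||^2), rows = points of X."""
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-w * d2)


@dataclass
class VectorFieldModel:
    """Fitted RKHS vector field: centers, coefficients, bandwidth."""

    centers: np.ndarray      # m x d
    coefficients: np.ndarray  # m x d
    w: float
    lam: float = 0.0
    fit_residual: float = float("nan")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Field value(s) at x (a point or a points x d matrix)."""
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 1
        out = _kernel(np.atleast_2d(x), self.centers, self.w) @ self.coefficients
        return out[0] if single else out

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian J_ij = dF_i/dx_j at a single point x.

        d/dx Gamma(x, c) = -2 w (x - c) Gamma(x, c), so
        J(x) = sum_a Gamma_a * coef_a (outer) (-2 w (x - c_a)).
        """
        x = np.asarray(x, dtype=np.float64).ravel()
        gamma = _kernel(x[None, :], self.centers, self.w)[0]  # (m,)
        diff = x[None, :] - self.centers                       # m x d
        # J = sum_a gamma_a * outer(coef_a, -2w diff_a)
        return -2.0 * self.w * np.einsum("a,ai,aj->ij", gamma, self.coefficients, diff)

    def jacobian_entry(self, X: np.ndarray, target: int, regulator: int) -> np.ndarray:
        """J[target, regulator] evaluated at every row of X (vectorized)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        K = _kernel(X, self.centers, self.w)                 # n x m
        diff_j = X[:, None, regulator] - self.centers[None, :, regulator]
        return -2.0 * self.w * (K * diff_j) @ self.coefficients[:, target]


def fit_rkhs_vectorfield(
    X: np.ndarray,
    V: np.ndarray,
    n_centers: Optional[int] = None,
    w: Optional[float] = None,
    lam: Optional[float] = None,
    seed: int = 0,
) -> VectorFieldModel:
    """Fit the Gaussian-basis vector field to sampled velocities.

    Centers are a seeded uniform subsample of the rows of X (default
    min(500, n/2)); the bandwidth default scales inversely with the squared
    median pairwise distance of the centers; lam defaults to 1e-3 of the
    kernel trace scale.  Deterministic given seed and data.
    """
    X = np.asarray(X, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if X.shape != V.shape:
        raise ValueError("X and V must have the same shape")
    n = X.shape[0]
    if n_centers is None:
        n_centers = min(500, max(n // 2, 1))
    n_centers = min(n_centers, n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=n_centers, replace=False))
    centers = X[idx]
    if w is None:
        d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        med = np.median(d2[np.triu_indices(n_centers, k=1)]) if n_centers > 1 else 1.0
        w = 1.0 / max(med, 1e-12)
    K = _kernel(X, centers, w)          # n x m
    G = _kernel(centers, centers, w)    # m x m
    KtK = K.T @ K
    if lam is None:
        # 1e-3 of the trace scale of the normal matrix
        lam = 1e-3 * float(np.trace(KtK)) / n_centers
    A = KtK + 0.5 * lam * G
    B = K.T @ V
    if lam == 0:
        try:
            coef = np.linalg.solve(A, B)
        except np.linalg.LinAlgError:
            warnings.warn("singular normal equations with lam=0; using pseudo-inverse",
                          RuntimeWarning)
            coef = np.linalg.pinv(A) @ B
    else:
        coef = np.linalg.solve(A, B)
    resid = float(np.linalg.norm(V - K @ coef))
    return VectorFieldModel(centers=centers, coefficients=coef, w=w,
                            lam=lam, fit_residual=resid)


@dataclass
class DoseResponseCurve:
    """Effective dose-response of a target on a regulator.

    ``bin_edges`` (n_bins + 1) span the regulator's observed range;
    ``bin_means`` are per-bin averages of the Jacobian element
    dF_target/dx_regulator over the sampled cell states; ``curve`` is the
    cumulative integral (n_bins + 1 values starting at ``f0``), defined up
    to the additive constant f0.
    """

    regulator: int
    target: int
    bin_edges: np.ndarray
    bin_means: np.ndarray
    curve: np.ndarray
    f0: float = 0.0


def dose_response(
    model: VectorFieldModel,
    X: np.ndarray,
    regulator: int,
    target: int,
    n_bins: int = 20,
    f0: float = 0.0,
    variance_warn_ratio: float = 2.0,
) -> DoseResponseCurve:
    """Reconstruct the effective dose-response curve of a regulator-target
    pair by binned integration of the Jacobian element.

    The Jacobian element J = dF_target/dx_regulator is evaluated at every
    sampled state, binned into ``n_bins`` equal-width bins of the regulator's
    value, bin-averaged, and cumulatively integrated (mean x bin width).
    Empty bins carry the previous bin's mean forward.  Permutation-invariant
    in the cell order.  Large within-bin variance (other factors modulating
    the response) triggers a logged warning suggesting to stratify cells
    first.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    xj = X[:, regulator]
    lo, hi = float(xj.min()), float(xj.max())
    if hi - lo <= 0:
        raise ValueError("regulator is constant across cells (zero-width range)")
    jvals = model.jacobian_entry(X, target=target, regulator=regulator)
    edges = np.linspace(lo, hi, n_bins + 1)
    width = (hi - lo) / n_bins
    which = np.clip(np.searchsorted(edges, xj, side="right") - 1, 0, n_bins - 1)
    means = np.zeros(n_bins)
    prev = 0.0
    warned = False
    for b in range(n_bins):
        vals = jvals[which == b]
        if vals.size == 0:
            means[b] = prev
            continue
        means[b] = vals.mean()
        if vals.size > 1:
            spread = vals.std()
            if spread > variance_warn_ratio * max(abs(means[b]), 1e-12) and not warned:
                logger.warning(
                    "large within-bin Jacobian variance for pair (%d -> %d); "
                    "consider clustering cells before dose-response reconstruction",
                    regulator, target,
                )
                warned = True
        prev = means[b]
    curve = f0 + np.concatenate([[0.0], np.cumsum(means) * width])
    return DoseResponseCurve(regulator=regulator, target=target,
                             bin_edges=edges, bin_means=means, curve=curve, f0=f0)
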