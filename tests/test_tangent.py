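import numpy as np
import pytest

import graphvelo as gv
from graphvelo.tangent import (
    LinearEmbedding,
    TSPConfig,
    adaptive_step_size,
    baseline_cosine_projection,
    cosine_kernel_weights,
    displacement_basis,
    fit_projection_weights,
    fit_tsp_weights,
    infer_unmeasured_velocity,
    project_velocities,
    transform_velocity,
    velocity_to_embedding,
)

from conftest import rowwise_cosine


def two_cell_pop():
    X = np.array([[0.0, 0.0], [1.0, 2.0]])
    g = gv.NeighborGraph([np.array([1]), np.array([0])],
                         [np.array([np.sqrt(5)])] * 2)
    return gv.CellPopulation(X=X), g


# -- displacement basis ------------------------------------------------------

def test_displacement_is_neighbor_minus_self():
    pop, g = two_cell_pop()
    deltas = displacement_basis(pop, g)
    np.testing.assert_allclose(deltas[0], [[1.0, 2.0]])
    np.testing.assert_allclose(deltas[1], [[-1.0, -2.0]])


def test_displacement_feature_subset_gives_scalars():
    pop, g = two_cell_pop()
    deltas = displacement_basis(pop, g, feature_subset=[1])
    assert deltas[0].shape == (1, 1) and deltas[0][0, 0] == 2.0


def test_displacement_matches_direct_subtraction(rng):
    X = rng.normal(size=(15, 6))
    pop = gv.CellPopulation(X=X)
    g = gv.build_knn(X, k=4)
    deltas = displacement_basis(pop, g, feature_subset=[0, 2, 5])
    for i in range(15):
        expected = X[np.ix_(g.indices[i], [0, 2, 5])] - X[i, [0, 2, 5]]
        np.testing.assert_allclose(deltas[i], expected)


# -- cosine kernel -----------------------------------------------------------

def test_cosine_kernel_identities():
    v = np.array([1.0, 0.0])
    deltas = np.array([[2.0, 0.0], [0.0, 3.0]])
    np.testing.assert_allclose(cosine_kernel_weights(v, deltas), [1.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(cosine_kernel_weights(-deltas[0], deltas), [-1.0, 0.0], atol=1e-12)


def test_cosine_kernel_zero_vectors_give_zero():
    assert cosine_kernel_weights(np.zeros(3), np.ones((2, 3))).tolist() == [0.0, 0.0]
    out = cosine_kernel_weights(np.ones(3), np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]))
    np.testing.assert_allclose(out, [0.0, 1.0], atol=1e-12)


def test_cosine_kernel_matches_dot_product_oracle(rng):
    v = rng.normal(size=7)
    deltas = rng.normal(size=(5, 7))
    expected = [d @ v / (np.linalg.norm(d) * np.linalg.norm(v)) for d in deltas]
    np.testing.assert_allclose(cosine_kernel_weights(v, deltas), expected, rtol=1e-12)


# -- TSP fitting -------------------------------------------------------------

def test_tsp_exact_when_v_in_span(rng):
    D = rng.normal(size=(4, 6))
    phi_true = rng.normal(size=4)
    v = phi_true @ D
    phi, _, _ = fit_tsp_weights(v, D, TSPConfig(a=1, b=0, lam=0))
    np.testing.assert_allclose(phi @ D, v, atol=1e-6 * np.linalg.norm(v))


def test_tsp_annihilates_orthogonal_component(rng):
    # v orthogonal to span(deltas) -> projection ~ 0
    D = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    v = np.array([0.0, 0.0, 5.0])
    phi, _, _ = fit_tsp_weights(v, D, TSPConfig(a=1, b=0, lam=1e-8))
    assert np.linalg.norm(phi @ D) < 1e-4 * np.linalg.norm(v)


def test_tsp_zero_velocity_returns_zero_weights():
    phi, loss, nit = fit_tsp_weights(np.zeros(3), np.eye(3), TSPConfig())
    assert np.all(phi == 0) and loss == 0 and nit == 0


def test_tsp_loss_never_worse_than_initialization(rng):
    cfg = TSPConfig()
    for _ in range(20):
        D = rng.normal(size=(5, 4))
        v = rng.normal(size=4)
        phi0 = np.linalg.solve(cfg.a * D @ D.T + cfg.lam * np.eye(5), cfg.a * D @ v)
        corr = cosine_kernel_weights(v, D)
        from graphvelo.tangent import _tsp_loss_grad

        loss0, _ = _tsp_loss_grad(phi0, D, v, corr, cfg)
        _, loss, _ = fit_tsp_weights(v, D, cfg)
        assert loss <= loss0 + 1e-12


def test_tsp_matches_dense_grid_search():
    """3-neighbor default-hyperparameter fit lands within grid resolution of
    an exhaustive search over phi in [-3, 3]^3 (step 0.01)."""
    rng = np.random.default_rng(0)
    D = rng.normal(size=(3, 3))
    v = rng.normal(size=3)
    cfg = TSPConfig(a=1, b=10, lam=1)
    phi_opt, loss_opt, _ = fit_tsp_weights(v, D, cfg)
    corr = cosine_kernel_weights(v, D)
    cn = np.linalg.norm(corr)
    axis = np.arange(-3.0, 3.0001, 0.01)
    grid23 = np.array(np.meshgrid(axis, axis, indexing="ij")).reshape(2, -1).T
    best = np.inf
    for p1 in axis:
        phi = np.column_stack([np.full(len(grid23), p1), grid23])
        resid = v[None, :] - phi @ D
        loss = cfg.a * (resid**2).sum(1) + cfg.lam * (phi**2).sum(1)
        pn = np.linalg.norm(phi, axis=1)
        cos = np.where(pn > 0, phi @ corr / (np.maximum(pn, 1e-300) * cn), 0.0)
        loss -= cfg.b * cos
        best = min(best, float(loss.min()))
    # optimizer at least matches the grid; grid can only be better by < its
    # own resolution
    assert loss_opt <= best + 1e-6
    assert best <= loss_opt + 0.01


def test_tsp_equals_ols_projection_oracle(rng):
    """With b=0, lam=0 the fit is the ordinary least-squares projection onto
    span(deltas) — checked against the normal-equations oracle on 100 random
    neighborhoods."""
    cfg = TSPConfig(a=1, b=0, lam=0)
    for _ in range(100):
        k = int(rng.integers(1, 11))
        d = int(rng.integers(max(1, k // 2), 11))
        D = rng.normal(size=(k, d))
        v = rng.normal(size=d)
        phi, _, _ = fit_tsp_weights(v, D, cfg)
        v_par = phi @ D
        # independent oracle: project v onto the row space of D via pinv
        v_ols = D.T @ np.linalg.pinv(D @ D.T) @ (D @ v)
        np.testing.assert_allclose(v_par, v_ols, atol=1e-6 * max(np.linalg.norm(v), 1e-12))


def test_tsp_masks_nan_velocity_dimensions(rng):
    D = rng.normal(size=(3, 4))
    phi_true = rng.normal(size=3)
    v = phi_true @ D
    v_masked = v.copy()
    v_masked[2] = np.nan
    phi, _, _ = fit_tsp_weights(v_masked, D, TSPConfig(a=1, b=0, lam=0))
    # weights are fitted on the observed dims but apply to all of them
    np.testing.assert_allclose((phi @ D)[[0, 1, 3]], v[[0, 1, 3]], atol=1e-8)


# -- projection at population level -----------------------------------------

def test_projection_is_fixed_point_for_tangent_inputs(rng):
    X = rng.normal(size=(30, 4))
    pop = gv.CellPopulation(X=X)
    g = gv.build_knn(X, k=5)
    deltas = displacement_basis(pop, g)
    V = np.vstack([rng.normal(size=5) @ deltas[i] for i in range(30)])
    pop.layers["velocity"] = V
    pop, _ = project_velocities(pop, g, TSPConfig(a=1, b=0, lam=0))
    np.testing.assert_allclose(pop.dense_layer("velocity_graphvelo"), V, atol=1e-6)


def test_projection_reconstructs_from_own_weights(rng):
    X = rng.normal(size=(25, 3))
    pop = gv.CellPopulation(X=X, layers={"velocity": rng.normal(size=(25, 3))})
    g = gv.build_knn(X, k=6)
    pop, weights = project_velocities(pop, g)
    V = pop.dense_layer("velocity_graphvelo")
    deltas = displacement_basis(pop, g)
    for i in range(25):
        np.testing.assert_allclose(V[i], weights.weights[i] @ deltas[i], atol=1e-8)


def test_projection_recovers_truth_on_clean_sphere(sphere_truth):
    pop = sphere_truth.to_population()
    g = gv.build_knn(pop.dense_X(), k=30)
    pop, _ = project_velocities(pop, g)
    cos = rowwise_cosine(pop.dense_layer("velocity_graphvelo"),
                         np.asarray(sphere_truth.velocities_true))
    assert np.median(cos) >= 0.99


# -- transformation ----------------------------------------------------------

def test_transform_to_source_coords_reproduces_projection(rng):
    X = rng.normal(size=(20, 3))
    pop = gv.CellPopulation(X=X, layers={"velocity": rng.normal(size=(20, 3))})
    g = gv.build_knn(X, k=4)
    pop, weights = project_velocities(pop, g)
    again = transform_velocity(weights, X, g)
    np.testing.assert_allclose(again, pop.dense_layer("velocity_graphvelo"), atol=1e-12)


def test_transform_is_exactly_equivariant_under_linear_maps(rng):
    X = rng.normal(size=(20, 4))
    pop = gv.CellPopulation(X=X, layers={"velocity": rng.normal(size=(20, 4))})
    g = gv.build_knn(X, k=5)
    pop, weights = project_velocities(pop, g)
    v_par = pop.dense_layer("velocity_graphvelo")
    A = rng.normal(size=(4, 6))
    np.testing.assert_allclose(transform_velocity(weights, X @ A, g), v_par @ A,
                               rtol=1e-12, atol=1e-12)


def test_transform_infers_linearly_dependent_feature(rng):
    """Fit on 2 velocity genes; in a 5-gene space where gene 3 is the sum of
    genes 1-2 across cells, the inferred gene-3 velocity is the sum of the
    inferred gene-1 and gene-2 velocities."""
    n = 40
    X2 = rng.normal(size=(n, 2))
    X5 = np.column_stack([X2, X2.sum(axis=1), rng.normal(size=n), rng.normal(size=n)])
    V = np.full((n, 5), np.nan)
    V[:, :2] = rng.normal(size=(n, 2))
    pop = gv.CellPopulation(X=X5, layers={"velocity": V})
    g = gv.build_knn(X5, k=6)
    out = infer_unmeasured_velocity(pop, g, source_features=[0, 1],
                                    target_features=[0, 1, 2])
    np.testing.assert_allclose(out[:, 2], out[:, 0] + out[:, 1], rtol=1e-10, atol=1e-10)


def test_transform_row_count_mismatch(rng):
    X = rng.normal(size=(10, 2))
    pop = gv.CellPopulation(X=X, layers={"velocity": rng.normal(size=(10, 2))})
    g = gv.build_knn(X, k=3)
    _, weights = project_velocities(pop, g)
    with pytest.raises(ValueError, match="row count"):
        transform_velocity(weights, np.zeros((11, 2)), g)


def test_infer_constant_target_feature_has_zero_velocity(rng):
    X = np.column_stack([rng.normal(size=(25, 2)), np.full(25, 3.0)])
    V = np.full((25, 3), np.nan)
    V[:, :2] = rng.normal(size=(25, 2))
    pop = gv.CellPopulation(X=X, layers={"velocity": V})
    g = gv.build_knn(X, k=5)
    out = infer_unmeasured_velocity(pop, g, source_features=[0, 1],
                                    target_features=[2])
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_hidden_sphere_coordinate_recovered_tangent(sphere_truth):
    pop = sphere_truth.to_population()
    V = pop.dense_layer("velocity").copy()
    V[:, 2] = np.nan
    pop.layers["velocity"] = V
    g = gv.build_knn(pop.dense_X(), k=30)
    v3 = infer_unmeasured_velocity(pop, g, source_features=[0, 1],
                                   target_features=[0, 1, 2])
    resid = np.abs((sphere_truth.states * v3).sum(axis=1)) / (
        70.0 * np.linalg.norm(v3, axis=1) + 1e-12)
    assert np.median(resid) < 0.05


# -- step size & embedding ---------------------------------------------------

def test_adaptive_step_on_regular_grid():
    X = np.arange(10, dtype=float)[:, None]
    V = np.full((10, 1), 2.0)
    pop = gv.CellPopulation(X=X, layers={"velocity": V})
    g = gv.build_knn(X, k=2)
    dt, ok = adaptive_step_size(pop, g)
    # interior cells: median neighbor distance 1, speed 2
    np.testing.assert_allclose(dt[1:-1], 0.5)
    assert ok.all()


def test_adaptive_step_zero_speed_is_undefined(rng):
    X = rng.normal(size=(5, 2))
    V = rng.normal(size=(5, 2))
    V[2] = 0.0
    pop = gv.CellPopulation(X=X, layers={"velocity": V})
    g = gv.build_knn(X, k=2)
    dt, ok = adaptive_step_size(pop, g)
    assert not ok[2] and np.isnan(dt[2])


def test_adaptive_step_matches_median_oracle(rng):
    X = rng.normal(size=(15, 3))
    V = rng.normal(size=(15, 3))
    pop = gv.CellPopulation(X=X, layers={"velocity": V})
    g = gv.build_knn(X, k=4)
    dt, _ = adaptive_step_size(pop, g)
    for i in range(15):
        med = np.median([np.linalg.norm(X[j] - X[i]) for j in g.indices[i]])
        assert np.isclose(dt[i], med / np.linalg.norm(V[i]))


def test_velocity_to_embedding_equals_vQ(rng):
    X = rng.normal(size=(20, 5))
    V = rng.normal(size=(20, 5))
    pop = gv.CellPopulation(X=X, layers={"velocity": V})
    g = gv.build_knn(X, k=4)
    Q, _ = np.linalg.qr(rng.normal(size=(5, 3)))
    emb = LinearEmbedding(loadings=Q)
    out = velocity_to_embedding(pop, emb, g)
    np.testing.assert_allclose(out, V @ Q, rtol=1e-8, atol=1e-8)


def test_full_rank_orthonormal_embedding_preserves_speed(rng):
    X = rng.normal(size=(15, 4))
    V = rng.normal(size=(15, 4))
    pop = gv.CellPopulation(X=X, layers={"velocity": V})
    g = gv.build_knn(X, k=3)
    Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    out = velocity_to_embedding(pop, LinearEmbedding(loadings=Q), g)
    np.testing.assert_allclose(np.linalg.norm(out, axis=1),
                               np.linalg.norm(V, axis=1), rtol=1e-8)


def test_rank_deficient_embedding_contracts_speed(rng):
    X = rng.normal(size=(15, 3))
    V = rng.normal(size=(15, 3))
    pop = gv.CellPopulation(X=X, layers={"velocity": V})
    g = gv.build_knn(X, k=3)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 2)))
    out = velocity_to_embedding(pop, LinearEmbedding(loadings=Q), g)
    assert np.all(np.linalg.norm(out, axis=1) <= np.linalg.norm(V, axis=1) + 1e-10)


# -- cosine baseline ---------------------------------------------------------

def test_baseline_single_parallel_neighbor():
    X = np.array([[0.0, 0.0], [1.0, 0.0]])
    V = np.array([[2.0, 0.0], [0.0, 0.0]])
    pop = gv.CellPopulation(X=X, layers={"velocity": V})
    g = gv.NeighborGraph([np.array([1]), np.array([0])], [np.array([1.0])] * 2)
    out = baseline_cosine_projection(pop, g)
    assert out[0, 0] > 0 and np.isclose(out[0, 1], 0.0)


def test_baseline_symmetric_opposing_neighbors_cancel():
    X = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
    V = np.array([[0.0, 1.0], [0.0, 0.0], [0.0, 0.0]])
    pop = gv.CellPopulation(X=X, layers={"velocity": V})
    g = gv.NeighborGraph(
        [np.array([1, 2]), np.array([0]), np.array([0])],
        [np.array([1.0, 1.0]), np.array([1.0]), np.array([1.0])],
    )
    out = baseline_cosine_projection(pop, g)
    np.testing.assert_allclose(out[0], 0.0, atol=1e-12)


def test_baseline_preserves_direction_but_not_speed(sphere_noisy, sphere_projected):
    pop, g, noisy = sphere_noisy
    truth = np.asarray(noisy.velocities_true)
    base = baseline_cosine_projection(pop, g)
    assert np.median(rowwise_cosine(base, truth)) >= 0.9
    speed_corr_base = np.corrcoef(np.linalg.norm(base, axis=1),
                                  np.linalg.norm(truth, axis=1))[0, 1]
    proj = sphere_projected[0].dense_layer("velocity_graphvelo")
    speed_corr_gv = np.corrcoef(np.linalg.norm(proj, axis=1),
                                np.linalg.norm(truth, axis=1))[0, 1]
    assert speed_corr_gv > speed_corr_base
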