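import numpy as np
import pytest

import graphvelo as gv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sphere_truth():
    """Noise-free toggle-switch bifurcation lifted onto the r=70 sphere."""
    res = gv.simulate_toggle_switch(gv.ToggleSwitchParams(seed=1))
    return gv.embed_on_sphere(res)


@pytest.fixture(scope="session")
def sphere_noisy(sphere_truth):
    """Sphere dataset with radial (off-manifold) velocity noise at the
    median-speed level, plus its kNN graph."""
    med_speed = float(np.median(np.linalg.norm(sphere_truth.velocities_true, axis=1)))
    noisy = gv.add_noise(sphere_truth, "orthogonal", level=med_speed, seed=2)
    pop = noisy.to_population()
    g = gv.build_knn(pop.dense_X(), k=30)
    return pop, g, noisy


@pytest.fixture(scope="session")
def sphere_projected(sphere_noisy):
    """Tangent-space projection of the noisy sphere velocities (defaults)."""
    pop, g, noisy = sphere_noisy
    pop, weights = gv.project_velocities(pop, g)
    return pop, g, weights


def radial_ratio(states, velocities, r=70.0):
    normals = states / np.linalg.norm(states, axis=1, keepdims=True)
    return np.abs((velocities * normals).sum(axis=1)) / (
        np.linalg.norm(velocities, axis=1) + 1e-12
    )


def rowwise_cosine(A, B):
    num = (A * B).sum(axis=1)
    den = np.linalg.norm(A, axis=1) * np.linalg.norm(B, axis=1)
    return num / np.where(den > 0, den, 1.0)
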