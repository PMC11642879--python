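# graphvelo

Manifold-constrained refinement and cross-representation transfer of
single-cell velocity vectors.

## The problem

RNA velocity estimators return, per cell, a vector of time derivatives of
gene expression. These vectors are noisy, are available only for a subset of
"velocity genes", and frequently point off the low-dimensional manifold that
the cell states actually occupy. Downstream analyses — transition scoring,
vector-field reconstruction, speed comparisons — inherit all of these
defects. The widely used cosine-kernel projection fixes the direction but
discards the magnitude of the velocity entirely.

`graphvelo` is for analysts who already have velocities from any upstream
estimator (splicing-based, metabolic-labeling-based, or simulated) and want
them (i) consistent with the data manifold, (ii) magnitude-preserving, and
(iii) transferable to other representations: principal-component spaces,
genes without velocity estimates, or a second modality such as chromatin
accessibility measured on the same cells.

## The model

The tangent space of the cell-state manifold at cell *i* is spanned, to first
order, by the displacements to its k nearest neighbors,
δ_ij = x_j − x_i. The measured velocity v_i is re-expressed as

    v∥(x_i) = Σ_{j∈N(i)} φ_ij δ_ij ,

with the weights φ_i found by minimizing the tangent-space-projection loss

    L(φ_i) = a‖v_i − Σ_j φ_ij δ_ij‖² − b·cos(φ_i, φ_i^corr) + λ‖φ_i‖² ,

where φ_i^corr are the cosine-kernel weights cos(v_i, δ_ij). The quadratic
term preserves magnitude, the cosine term anchors the direction to the
asymptotically correct kernel estimate, and the ridge term bounds the
weights (defaults a=1, b=10, λ=1). Because φ_i are coordinates in the local
displacement basis, the same weights re-express the velocity in **any** other
coordinate system of the same cells by swapping the basis:
v∥(y_i) = Σ_j φ_ij (y_j − y_i). This is how velocities are carried into
embeddings, inferred for unmeasured genes, or transferred from RNA to
chromatin-accessibility features.

The package also provides the evaluation scores used to benchmark velocity
fields (MacK manifold-consistency score, cross-boundary correctness, velocity
consistency, cell speed, and cell-specific kinetic rates α = u + du/dt,
γ = (u − ds/dt)/s), ODE/SDE simulators with exact ground-truth velocities
(toggle-switch bifurcation on a sphere, microRNA-driven variable degradation,
transcription bursts), an RKHS Gaussian-basis vector field with analytic
Jacobians and effective dose–response reconstruction, and velocity-trend
analysis (P-spline smoothing, Leiden trend clustering, DTW decoupling
detection).

## Worked example

```python
import numpy as np
import graphvelo as gv

# simulate a bifurcating two-gene system on a curved manifold
res = gv.simulate_toggle_switch(gv.ToggleSwitchParams(seed=1))
sphere = gv.embed_on_sphere(res)                       # radius-70 sphere
speed = np.linalg.norm(sphere.velocities_true, axis=1)
noisy = gv.add_noise(sphere, "orthogonal", level=np.median(speed), seed=2)

pop = noisy.to_population()
graph = gv.build_knn(pop.dense_X(), k=30)
pop, weights = gv.project_velocities(pop, graph)       # a=1, b=10, lam=1
refined = pop.dense_layer("velocity_graphvelo")

normals = sphere.states / 70.0
off = lambda V: np.median(np.abs((V * normals).sum(1)) / np.linalg.norm(V, axis=1))
print(f"off-manifold fraction: {off(noisy.velocities):.3f} -> {off(refined):.3f}")
r = np.corrcoef(np.linalg.norm(refined, axis=1), speed)[0, 1]
print(f"speed correlation with ground truth: {r:.3f}")

consistency = gv.velocity_consistency(pop, graph, vkey="velocity_graphvelo")
print(f"median velocity consistency: {np.median(consistency):.3f}")
```

Output:

```
off-manifold fraction: 0.591 -> 0.004
speed correlation with ground truth: 0.997
median velocity consistency: 0.987
```

The injected noise points radially off the sphere (59% of each vector's
norm, median); projection onto the neighbor-displacement span removes it
(0.4%) while keeping per-cell speeds correlated with the ground truth at
r = 0.997 — the cosine-kernel baseline on the same data reaches r ≈ 0.43
because its normalization discards magnitude.

The same machinery runs from the shell:

```sh
graphvelo simulate --model toggle-sphere --seed 1 --noise-mode orthogonal \
    --noise-level 6.4 --out sim.h5ad
graphvelo project --input sim.h5ad --output proj.h5ad
graphvelo scores --input proj.h5ad --output scores.csv --which consistency,speed
```

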