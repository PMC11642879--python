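"""Synthetic data generators with exact ground-truth velocities.

Four generators used to validate manifold-constrained velocity inference:

* a two-gene toggle-switch bifurcation (mutual inhibition + self activation,
  Hill kinetics) simulated stochastically, with the deterministic drift at
  each sampled state as the ground-truth velocity;
* a lift of the 2-d bifurcation onto a sphere of radius 70, where the third
  coordinate and its exact tangent velocity follow from the constraint
  z = sqrt(r^2 - x^2 - y^2) — a curved 2-d manifold embedded in 3-d;
* splicing ODE trajectories in which a rising microRNA signal simultaneously
  suppresses transcription and accelerates degradation (rapid-degradation
  phase portraits that defeat constant-rate splicing models);
* transcription-burst trajectories (alpha jumps threefold at a burst time).

Velocity noise can be injected either isotropically (Gaussian per coordinate)
or orthogonally to the manifold (along the sphere's radial normal), the
regime used for tangent-projection benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ToggleSwitchParams",
    "SphereEmbedConfig",
    "DegradationParams",
    "SimulationResult",
    "toggle_switch_drift",
    "simulate_toggle_switch",
    "embed_on_sphere",
    "add_noise",
    "simulate_variable_degradation",
    "simulate_transcription_burst",
]


@dataclass
class ToggleSwitchParams:
    """Rates of the mutually inhibiting / self-activating two-gene switch.

    dx/dt = a1 x^n / (S1^n + x^n) + b1 K1^n / (K1^n + y^n) - g1 x   (and
    symmetrically for y).  Defaults are chosen so that the two stable branches
    sit near (56, 1) and (1, 56): states then span a meaningful fraction of
    the radius-70 sphere used by :func:`embed_on_sphere` and the lifted
    manifold is genuinely curved.  Timescale tau = 1.
    """

    a1: float = 30.0
    a2: float = 30.0
    b1: float = 30.0
    b2: float = 30.0
    S1: float = 35.0
    S2: float = 35.0
    K1: float = 25.0
    K2: float = 25.0
    n: float = 4.0
    gamma1: float = 1.0
    gamma2: float = 1.0
    n_cells: int = 2000
    seed: int = 0
    tau: float = 1.0
    noise_scale: float = 1.0  # SDE noise amplitude (Euler-Maruyama)
    t_max: float = 10.0

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "b1", "b2", "S1", "S2", "K1", "K2",
                     "gamma1", "gamma2", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n < 1:
            raise ValueError("Hill exponent n must be >= 1")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")


def toggle_switch_drift(xy: np.ndarray, p: ToggleSwitchParams) -> np.ndarray:
    """Deterministic drift of the toggle switch at states xy (cells x 2)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
    x, y = xy[:, 0], xy[:, 1]
    n = p.n
    xn, yn = np.maximum(x, 0.0) ** n, np.maximum(y, 0.0) ** n
    dx = p.a1 * xn / (p.S1**n + xn) + p.b1 * p.K1**n / (p.K1**n + yn) - p.gamma1 * x
    dy = p.a2 * yn / (p.S2**n + yn) + p.b2 * p.K2**n / (p.K2**n + xn) - p.gamma2 * y
    return np.stack([dx, dy], axis=1) / p.tau


@dataclass
class SimulationResult:
    """Sampled states with exact ground-truth velocities.

    ``velocities`` is the working copy handed to inference (possibly noisy);
    ``velocities_true`` always keeps the exact drift.  ``normals`` holds unit
    manifold normals when the states live on a known surface.
    """

    states: np.ndarray
    velocities: np.ndarray
    times: np.ndarray
    labels: np.ndarray
    velocities_true: Optional[np.ndarray] = None
    normals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.float64)
        self.velocities = np.asarray(self.velocities, dtype=np.float64)
        if self.velocities_true is None:
            self.velocities_true = self.velocities.copy()
        if self.states.shape != self.velocities.shape:
            raise ValueError("states and velocities must have the same shape")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]

    def to_population(self):
        from .core_data import CellPopulation
        import pandas as pd

        obs = pd.DataFrame(
            {"time": self.times, "label": self.labels},
            index=pd.RangeIndex(self.n_cells).astype(str),
        )
        return CellPopulation(
            X=self.states,
            layers={
                "velocity": self.velocities.copy(),
                "velocity_true": np.asarray(self.velocities_true).copy(),
            },
            obs=obs,
        )


def toggle_switch_fixed_point(p: ToggleSwitchParams, branch: str = "x") -> np.ndarray:
    """Locate a stable branch fixed point by alternating 1-d root finding."""
    hi, lo = (60.0, 1.0) if branch == "x" else (1.0, 60.0)
    state = np.array([hi, lo])
    for _ in range(200):
        x, y = state

        def fx(xx):
            return float(toggle_switch_drift([[xx, y]], p)[0, 0])

        def fy(yy):
            return float(toggle_switch_drift([[x, yy]], p)[0, 1])

        x_new = brentq(fx, 1e-9, 1e3)
        y_new = brentq(fy, 1e-9, 1e3)
        if abs(x_new - x) < 1e-12 and abs(y_new - y) < 1e-12:
            state = np.array([x_new, y_new])
            break
        state = np.array([x_new, y_new])
    return state


def simulate_toggle_switch(p: Optional[ToggleSwitchParams] = None) -> SimulationResult:
    """Stochastic toggle-switch trajectories sampled to n_cells states.

    Trajectories start near the origin (both genes off), rise under basal
    induction, and commit to one of the two branches as multiplicative noise
    breaks the symmetry (Euler-Maruyama on the Hill drift).  The ground-truth
    velocity at each sampled state is the deterministic drift evaluated
    there.  Fully seed-deterministic.
    """
    p = p or ToggleSwitchParams()
    rng = np.random.default_rng(p.seed)
    n_record = 40
    n_traj = int(np.ceil(p.n_cells / n_record))
    dt = 0.01
    n_steps = int(p.t_max / dt)
    record_every = max(n_steps // n_record, 1)

    states, times = [], []
    for _ in range(n_traj):
        xy = np.abs(rng.normal(1.0, 0.3, size=2))
        t = 0.0
        for step in range(n_steps):
            drift = toggle_switch_drift(xy[None, :], p)[0]
            # multiplicative noise: fluctuation grows with copy number
            sigma = p.noise_scale * np.sqrt(np.maximum(xy, 0.2))
            xy = xy + drift * dt + sigma * np.sqrt(dt) * rng.standard_normal(2)
            xy = np.maximum(xy, 0.0)
            t += dt
            if (step + 1) % record_every == 0:
                states.append(xy.copy())
                times.append(t)
    states = np.asarray(states)[: p.n_cells]
    times = np.asarray(times)[: p.n_cells]
    velocities = toggle_switch_drift(states, p)
    labels = np.where(states[:, 0] >= states[:, 1], "branch_x", "branch_y")
    return SimulationResult(states=states, velocities=velocities,
                            times=times, labels=labels)


@dataclass
class SphereEmbedConfig:
    """Sphere lift: radius r (default 70) and the finite-difference step dt
    (default 1) used to propagate states when computing the z velocity."""

    r: float = 70.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.dt <= 0:
            raise ValueError("r and dt must be > 0")


def _sphere_z(x: np.ndarray, y: np.ndarray, r: float) -> np.ndarray:
    return np.sqrt(np.maximum(r**2 - x**2 - y**2, 0.0))


def embed_on_sphere(
    res2d: SimulationResult, cfg: Optional[SphereEmbedConfig] = None
) -> SimulationResult:
    """Lift 2-d states (x, y) onto the upper hemisphere z = sqrt(r^2-x^2-y^2).

    The z velocity is obtained by propagating the 2-d state one step dt and
    differencing the lifted coordinate:
    zdot = (z(x + xdot dt, y + ydot dt) - z(x, y)) / dt, which converges to
    the analytic tangent derivative -(x xdot + y ydot)/z as dt -> 0.  Radial
    unit normals are attached for orthogonal noise injection.
    """
    cfg = cfg or SphereEmbedConfig()
    if res2d.states.shape[1] != 2:
        raise ValueError("embed_on_sphere requires 2-d input states")
    x, y = res2d.states[:, 0], res2d.states[:, 1]
    vx, vy = res2d.velocities_true[:, 0], res2d.velocities_true[:, 1]
    z = _sphere_z(x, y, cfg.r)
    z_next = _sphere_z(x + vx * cfg.dt, y + vy * cfg.dt, cfg.r)
    vz = (z_next - z) / cfg.dt
    states = np.stack([x, y, z], axis=1)
    velocities = np.stack([vx, vy, vz], axis=1)
    normals = states / np.linalg.norm(states, axis=1, keepdims=True)
    return SimulationResult(
        states=states,
        velocities=velocities,
        times=res2d.times,
        labels=res2d.labels,
        normals=normals,
    )


def add_noise(
    res: SimulationResult, mode: str, level: float, seed: int = 0
) -> SimulationResult:
    """Inject noise into the velocity vectors, keeping the truth aside.

    ``gaussian`` adds i.i.d. N(0, level^2) per coordinate; ``orthogonal``
    adds eps * n_hat with eps ~ N(0, level^2) along the manifold normal
    (requires ``res.normals``), emulating off-manifold measurement error.
    """
    rng = np.random.default_rng(seed)
    truth = np.asarray(res.velocities_true)
    if mode == "gaussian":
        noisy = truth + rng.normal(0.0, level, size=truth.shape)
    elif mode == "orthogonal":
        if res.normals is None:
            raise ValueError("orthogonal noise requires a manifold normal field")
        eps = rng.normal(0.0, level, size=truth.shape[0])
        noisy = truth + eps[:, None] * res.normals
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    return SimulationResult(
        states=res.states.copy(),
        velocities=noisy,
        times=res.times.copy(),
        labels=np.asarray(res.labels).copy(),
        velocities_true=truth.copy(),
        normals=None if res.normals is None else res.normals.copy(),
    )


@dataclass
class DegradationParams:
    """Rates of the microRNA-coupled splicing model.

    dm/dt = alpha_m - gamma_m m
    du/dt = (alpha0 - k_alpha m) - beta u
    ds/dt = beta u - (gamma0 + k_gamma m) s

    The signal m rises from 0 toward alpha_m/gamma_m, simultaneously lowering
    the transcription rate and raising the degradation constant, producing
    the rapid-degradation phase portrait.  Defaults are repo fixture values
    satisfying k_alpha * max(m) < alpha0 (non-negative transcription).
    """

    alpha0: float = 10.0
    beta: float = 1.0
    gamma0: float = 1.0
    k_alpha: float = 2.0
    k_gamma: float = 3.0
    alpha_m: float = 1.0
    gamma_m: float = 0.5
    t_max: float = 10.0
    n_steps: int = 400

    def __post_init__(self) -> None:
        for name in ("alpha0", "beta", "gamma0", "alpha_m", "gamma_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_alpha * self.alpha_m / self.gamma_m >= self.alpha0:
            raise ValueError("k_alpha * m_max must stay below alpha0")


@dataclass
class KineticTrajectory:
    """Deterministic (u, s) trajectory with exact derivatives and, when the
    model includes a microRNA signal, its level m."""

    t: np.ndarray
    u: np.ndarray
    s: np.ndarray
    du_dt: np.ndarray
    ds_dt: np.ndarray
    m: Optional[np.ndarray] = None
    params: object = None


def simulate_variable_degradation(p: Optional[DegradationParams] = None) -> KineticTrajectory:
    """Integrate the microRNA-coupled splicing ODEs from the unperturbed
    steady state u0 = alpha0/beta, s0 = alpha0/gamma0, m0 = 0.

    Deterministic adaptive Runge-Kutta integration (rtol 1e-8); returns the
    states with the exact instantaneous derivatives evaluated from the
    right-hand side.
    """
    p = p or DegradationParams()

    def rhs(t, y):
        m, u, s = y
        return [
            p.alpha_m - p.gamma_m * m,
            (p.alpha0 - p.k_alpha * m) - p.beta * u,
            p.beta * u - (p.gamma0 + p.k_gamma * m) * s,
        ]

    t_eval = np.linspace(0.0, p.t_max, p.n_steps)
    y0 = [0.0, p.alpha0 / p.beta, p.alpha0 / p.gamma0]
    sol = solve_ivp(rhs, (0.0, p.t_max), y0, t_eval=t_eval,
                    rtol=1e-8, atol=1e-10, method="RK45")
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    m, u, s = sol.y
    derivs = np.asarray([rhs(t, y) for t, y in zip(sol.t, sol.y.T)])
    return KineticTrajectory(
        t=sol.t, u=u, s=s, du_dt=derivs[:, 1], ds_dt=derivs[:, 2],
        m=m, params=p,
    )


def simulate_transcription_burst(
    alpha: float = 2.0,
    beta: float = 1.0,
    gamma: float = 1.0,
    t_burst: float = 10.0,
    fold: float = 3.0,
    t_max: float = 20.0,
    n_steps: int = 400,
) -> KineticTrajectory:
    """Splicing trajectory with a transcription burst.

    From u0 = s0 = 0 the gene approaches the steady state u = alpha/beta;
    at ``t_burst`` the transcription rate jumps to ``fold * alpha`` (default
    threefold) and the system relaxes toward the new asymptote.  Degradation
    stays constant.  Integrated piecewise so the rate discontinuity is exact.
    """
    if t_burst >= t_max:
        raise ValueError("t_burst must be < t_max")

    def rhs(t, y, a):
        u, s = y
        return [a - beta * u, beta * u - gamma * s]

    t_eval = np.linspace(0.0, t_max, n_steps)
    pre_mask = t_eval <= t_burst
    sol1 = solve_ivp(rhs, (0.0, t_burst), [0.0, 0.0], args=(alpha,),
                     t_eval=t_eval[pre_mask], rtol=1e-8, atol=1e-10,
                     dense_output=True)
    y_burst = sol1.sol(t_burst)
    sol2 = solve_ivp(rhs, (t_burst, t_max), list(y_burst), args=(fold * alpha,),
                     t_eval=t_eval[~pre_mask], rtol=1e-8, atol=1e-10)
    u = np.concatenate([sol1.y[0], sol2.y[0]])
    s = np.concatenate([sol1.y[1], sol2.y[1]])
    a_vec = np.where(pre_mask, alpha, fold * alpha)
    du = a_vec - beta * u
    ds = beta * u - gamma * s
    return KineticTrajectory(t=t_eval, u=u, s=s, du_dt=du, ds_dt=ds,
                             params=dict(alpha=alpha, beta=beta, gamma=gamma,
                                         t_burst=t_burst, fold=fold))
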