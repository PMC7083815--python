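"""Euler-Maruyama integration of the compartmentalised stochastic systems.

Two integrators are provided: :func:`simulate_linear` for the scaled
perturbation dynamics d(dx) = A dx dt + eta dt (the object the analytic
spectra describe) and :func:`simulate_nonlinear` for the full mass-action
reaction-diffusion system with inflow noise scaled by Omega^(-1/2).  The
physical concentration field is x = x* + Omega^(-1/2) dx.

Time discretisation.  The noise is sampled (and the state recorded) on a
grid of step ``dt``; within each noise step the deterministic part is
advanced by ``substeps`` explicit Euler-Maruyama sub-steps with eta held
constant.  Sub-stepping is required because the diffusion part of A is
stiff -- on the reference grid its fastest eigenvalue is about -6.4e3, so
an explicit step must stay below ~3e-4 while the physics (and every noise
colour studied) lives at frequencies of order one.  ``substeps=None``
picks the sub-step count automatically from max |Re lambda(A)|.

Noise records are drawn up front from the samplers in :mod:`crnoise.noise`
with one independent stream per repetition (spawned from a single seed),
so a linear and a nonlinear run with the same seed experience the same
noise path -- the weak-noise consistency check relies on this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .crn import ReactionNetwork, inflow_rates
from .linear_model import SpatialGrid
from .noise import NoiseModel, apply_truncation, sample_noise

__all__ = [
    "Trajectory",
    "simulate_linear",
    "simulate_nonlinear",
    "reconstruct_pattern",
    "to_perturbation",
]

_BLOWUP_FACTOR = 1e8


@dataclass
class Trajectory:
    """Time series of the compartmentalised state for one repetition."""

    times: np.ndarray  # (n_steps + 1,)
    data: np.ndarray  # (n_steps + 1, n_species, K)
    representation: str  # "perturbation" (scaled dx) | "concentration"
    seed: int | None = None
    rep: int = 0
    noise: dict = field(default_factory=dict)
    clipped_fraction: float = 0.0  # truncation diagnostic
    negative_steps: int = 0  # nonlinear runs: recorded steps with any x < 0
    min_value: float = np.inf

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Data restricted to the half-open interval [t0, t1).

        Half-open so that a window of length T_w holds exactly T_w/dt
        samples and its Fourier grid coincides with omega_grid(T_w, dt).
        """
        sel = (self.times >= t0 - 1e-12) & (self.times < t1 - 1e-12)
        return self.data[sel]


def _rep_rngs(
    seed, reps: int, rep_offset: int = 0
) -> tuple[list[np.random.Generator], int | None]:
    """Counter-based per-repetition streams from one run seed.

    Repetition r (globally, including *rep_offset*) always receives the
    stream SeedSequence(seed).spawn(...)[r], so simulating repetitions one
    at a time reproduces a batched run bit for bit.
    """
    if isinstance(seed, np.random.Generator):
        # caller supplied a generator: spawn children for independence
        return (
            [np.random.default_rng(s) for s in seed.bit_generator.seed_seq.spawn(reps)],
            None,
        )
    base = 0 if seed is None else int(seed)
    ss = np.random.SeedSequence(base)
    children = ss.spawn(rep_offset + reps)[rep_offset:]
    return [np.random.default_rng(s) for s in children], base


def _auto_substeps(max_decay_rate: float, dt: float) -> int:
    """Sub-step count keeping dt_fine * max|Re lambda| <= 1 (half the
    explicit-Euler stability bound)."""
    return max(1, int(np.ceil(dt * max_decay_rate)))


def _check_substep_stability(max_decay_rate: float, dt_fine: float) -> None:
    bound = 2.0 / max_decay_rate if max_decay_rate > 0 else np.inf
    if dt_fine >= bound:
        raise ValueError(
            f"fine step {dt_fine:.3e} violates the explicit-scheme stability "
            f"bound {bound:.3e}; increase substeps"
        )


def simulate_linear(
    A: np.ndarray,
    noise_model: NoiseModel,
    grid: SpatialGrid,
    T: float,
    dt: float,
    seed=None,
    reps: int = 1,
    *,
    substeps: int | None = None,
    rep_offset: int = 0,
    inflow: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    initial: str = "auto",
    check_stability: bool = True,
) -> list[Trajectory]:
    """Integrate d(dx) = A dx dt + eta dt for *reps* repetitions.

    *inflow* (per-species deterministic inflow rates) is only needed when
    the noise model requests truncation.

    Initial condition: ``initial="stationary"`` draws dx(0) from the exact
    stationary Gaussian law (algebraic Lyapunov covariance; white noise
    only, where that law is available in closed form), so the record is
    stationary from t = 0; ``"zero"`` starts at rest and relies on burn-in;
    ``"auto"`` (default) picks stationary for white noise and zero
    otherwise.  An explicit *x0* (shape (n, K)) overrides both.
    """
    n = noise_model.n
    K = grid.n_compartments
    if A.shape != (n * K, n * K):
        raise ValueError(f"operator must be {(n * K, n * K)}, got {A.shape}")
    n_steps = int(round(T / dt))
    if n_steps < 1:
        raise ValueError("horizon shorter than one step")

    lam = np.linalg.eigvals(A)
    if check_stability and lam.real.max() >= 0:
        raise ValueError(
            f"operator has a non-decaying eigenvalue (max Re = {lam.real.max():.3e}); "
            "stationary simulation is invalid"
        )
    rate = float(np.abs(lam.real).max())
    if substeps is None:
        substeps = _auto_substeps(rate, dt)
    dt_fine = dt / substeps
    if check_stability:
        _check_substep_stability(rate, dt_fine)

    if initial not in ("auto", "zero", "stationary"):
        raise ValueError(f"unknown initial condition mode {initial!r}")
    if initial == "auto":
        initial = "stationary" if noise_model.variant == "white" else "zero"
    init_factor = None
    if x0 is None and initial == "stationary":
        if noise_model.variant != "white":
            raise ValueError(
                "the exact stationary law is only available for white noise"
            )
        from scipy.linalg import solve_continuous_lyapunov

        mask = (
            np.diag(np.asarray(noise_model.mask, dtype=float))
            if noise_model.mask is not None
            else np.eye(n)
        )
        Bm = mask @ noise_model.covariance @ mask
        C = solve_continuous_lyapunov(A, -np.kron(Bm, np.eye(K)))
        w, V = np.linalg.eigh(0.5 * (C + C.T))
        init_factor = V * np.sqrt(np.clip(w, 0.0, None))

    rngs, base_seed = _rep_rngs(seed, reps, rep_offset)
    out: list[Trajectory] = []
    for rep, rng in enumerate(rngs, start=rep_offset):
        record = sample_noise(noise_model, n_steps, dt, rng, n_sites=K)
        frac = 0.0
        if noise_model.truncate:
            if inflow is None:
                raise ValueError("truncation requires the deterministic inflow rates")
            record, frac = apply_truncation(record, inflow, noise_model.omega_strength)
        flat = record.reshape(n_steps, n * K)
        if x0 is not None:
            x = np.asarray(x0, dtype=float).reshape(n * K).copy()
        elif init_factor is not None:
            x = init_factor @ rng.standard_normal(n * K)
        else:
            x = np.zeros(n * K)
        scale0 = max(1.0, np.linalg.norm(x))
        data = np.empty((n_steps + 1, n * K))
        data[0] = x
        drift = np.empty_like(x)
        for t in range(n_steps):
            eta_dt = dt_fine * flat[t]
            for _ in range(substeps):
                np.dot(A, x, out=drift)
                drift *= dt_fine
                x = x + drift + eta_dt
            data[t + 1] = x
            if t % 1000 == 999 and np.linalg.norm(x) > _BLOWUP_FACTOR * scale0:
                raise RuntimeError(
                    f"linear integration diverged at t = {(t + 1) * dt:.3f}"
                )
        out.append(
            Trajectory(
                times=np.arange(n_steps + 1) * dt,
                data=data.reshape(n_steps + 1, n, K),
                representation="perturbation",
                seed=base_seed,
                rep=rep,
                noise=noise_model.describe(),
                clipped_fraction=frac,
            )
        )
    return out


def _reflecting_laplacian(x: np.ndarray, ds: float, out: np.ndarray) -> np.ndarray:
    """Discrete Neumann Laplacian of a (n, K) field via ghost points."""
    out[:, 1:-1] = x[:, 2:] + x[:, :-2] - 2.0 * x[:, 1:-1]
    out[:, 0] = x[:, 1] - x[:, 0]
    out[:, -1] = x[:, -2] - x[:, -1]
    out /= ds**2
    return out


def simulate_nonlinear(
    network: ReactionNetwork,
    params: Mapping[str, float],
    D: np.ndarray,
    grid: SpatialGrid,
    noise_model: NoiseModel,
    T: float,
    dt: float,
    seed=None,
    reps: int = 1,
    *,
    substeps: int | None = None,
    rep_offset: int = 0,
    x0: np.ndarray | None = None,
    clip_negative: bool = False,
) -> list[Trajectory]:
    """Integrate the full mass-action reaction-diffusion SPDE.

    dx_a/dt = D_a lap(x_a) + f_a(x) + Omega^(-1/2) eta_a per compartment.
    Negative concentrations are *reported*, not silently repaired (they
    diagnose breakdown of the weak-noise linear theory); set
    ``clip_negative=True`` to clamp the state at zero instead.
    """
    n, K = network.n, grid.n_compartments
    if noise_model.n != n:
        raise ValueError("noise covariance dimension must match species count")
    D = np.asarray(D, dtype=float).ravel()
    k = network.rate_vector(params)
    m1 = network.m1.astype(float)
    m2 = network.m2
    n_steps = int(round(T / dt))
    ds = grid.delta_s
    amp = 1.0 / np.sqrt(noise_model.omega_strength)
    k_in = inflow_rates(network, params)

    # stiffness estimate for auto sub-stepping: pure-diffusion worst rate
    diff_rate = 4.0 * D.max() / ds**2
    if substeps is None:
        substeps = _auto_substeps(diff_rate, dt)
    dt_fine = dt / substeps
    _check_substep_stability(diff_rate, dt_fine)

    rngs, base_seed = _rep_rngs(seed, reps, rep_offset)
    out: list[Trajectory] = []
    for rep, rng in enumerate(rngs, start=rep_offset):
        record = sample_noise(noise_model, n_steps, dt, rng, n_sites=K)
        frac = 0.0
        if noise_model.truncate:
            record, frac = apply_truncation(record, k_in, noise_model.omega_strength)
        if x0 is None:
            raise ValueError(
                "x0 is required (pass the steady state for a quiescent start)"
            )
        x0a = np.asarray(x0, dtype=float)
        if x0a.size == n:  # uniform profile from a species vector
            x = np.repeat(x0a.reshape(n, 1), K, axis=1)
        else:
            x = x0a.reshape(n, K).copy()
        scale0 = max(1.0, np.linalg.norm(x))
        data = np.empty((n_steps + 1, n, K))
        data[0] = x
        lap = np.empty_like(x)
        negative_steps = 0
        min_value = float(x.min())
        for t in range(n_steps):
            eta_dt = (dt_fine * amp) * record[t]
            for _ in range(substeps):
                # mass-action kinetics per compartment: m1 diag(k) x^m2
                mono = np.prod(x[None, :, :] ** m2[:, :, None], axis=1)  # (M, K)
                f = m1 @ (k[:, None] * mono)
                _reflecting_laplacian(x, ds, lap)
                x = x + dt_fine * (D[:, None] * lap + f) + eta_dt
                if clip_negative:
                    np.clip(x, 0.0, None, out=x)
            if np.any(x < 0):
                negative_steps += 1
                min_value = min(min_value, float(x.min()))
            data[t + 1] = x
            if t % 1000 == 999 and (
                not np.all(np.isfinite(x))
                or np.linalg.norm(x) > _BLOWUP_FACTOR * scale0
            ):
                raise RuntimeError(
                    f"nonlinear integration diverged at t = {(t + 1) * dt:.3f}"
                )
        out.append(
            Trajectory(
                times=np.arange(n_steps + 1) * dt,
                data=data,
                representation="concentration",
                seed=base_seed,
                rep=rep,
                noise=noise_model.describe(),
                clipped_fraction=frac,
                negative_steps=negative_steps,
                min_value=min_value,
            )
        )
    return out


def reconstruct_pattern(
    traj: Trajectory, xstar: np.ndarray, omega_strength: float
) -> Trajectory:
    """Physical concentrations x = x* + Omega^(-1/2) dx from a perturbation
    trajectory.  Quadrupling Omega halves the pattern amplitude exactly."""
    if traj.representation != "perturbation":
        raise ValueError("expected a perturbation (scaled dx) trajectory")
    xstar = np.asarray(xstar, dtype=float).reshape(1, -1, 1)
    data = xstar + traj.data / np.sqrt(omega_strength)
    return Trajectory(
        times=traj.times,
        data=data,
        representation="concentration",
        seed=traj.seed,
        rep=traj.rep,
        noise=traj.noise,
        clipped_fraction=traj.clipped_fraction,
        negative_steps=int(np.sum(np.any(data < 0, axis=(1, 2)))),
        min_value=float(data.min()),
    )


def to_perturbation(
    traj: Trajectory, xstar: np.ndarray, omega_strength: float
) -> Trajectory:
    """Scaled perturbation dx = sqrt(Omega) (x - x*) from a concentration
    trajectory (inverse of :func:`reconstruct_pattern`)."""
    if traj.representation != "concentration":
        raise ValueError("expected a concentration trajectory")
    xstar = np.asarray(xstar, dtype=float).reshape(1, -1, 1)
    data = np.sqrt(omega_strength) * (traj.data - xstar)
    return Trajectory(
        times=traj.times,
        data=data,
        representation="perturbation",
        seed=traj.seed,
        rep=traj.rep,
        noise=traj.noise,
        clipped_fraction=traj.clipped_fraction,
    )
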