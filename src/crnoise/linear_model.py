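"""Linearisation, compartmentalisation and analytic power spectra.

The reaction-diffusion system is linearised about its unique positive
steady state ``x*`` and discretised into K compartments on [0, L] with
reflecting (homogeneous Neumann) boundaries, giving the nK-dimensional
linear SDE

    d(dx) = A dx dt + eta dt,      A = D/ds^2 (discrete Laplacian) + J,

in species-major block layout.  The half-sample discrete cosine basis
cos(kappa_m ds (j - 1/2)), kappa_m = m pi / L, diagonalises the Laplacian
exactly, so each spatial mode m evolves independently under the
n x n mode matrix

    A_kappa = J + (2 D / ds^2) (cos(kappa_m ds) - 1).

For stationary forcing with spectral matrix N(omega) the per-mode power
spectrum is the real diagonal of Phi^-1 N Phi^-dagger with
Phi = -[A_kappa + i omega].  The prediction is valid only while every
mode matrix is Hurwitz stable, i.e. outside the Turing-unstable regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root


from .crn import ReactionNetwork, mass_action_jacobian, mass_action_rhs

__all__ = [
    "SpatialGrid",
    "LinearizedSystem",
    "SpectrumTable",
    "UnstableModeError",
    "steady_state",
    "jacobian",
    "laplacian_matrix",
    "assemble_A",
    "mode_matrix",
    "mode_matrices",
    "max_mode_growth_rate",
    "omega_grid",
    "analytic_spectrum",
    "eigenmodes",
    "linearize",
]


class UnstableModeError(RuntimeError):
    """A spatial mode has a non-negative growth rate: the parameters are in
    (or on the edge of) the Turing-unstable regime, where the linear
    stationary-spectrum analysis is invalid."""


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform 1-D compartment grid with reflecting Neumann boundaries."""

    length: float
    n_compartments: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("domain length must be positive")
        if self.n_compartments < 1:
            raise ValueError("need at least one compartment")

    @property
    def delta_s(self) -> float:
        return self.length / self.n_compartments

    @property
    def nodes(self) -> np.ndarray:
        """Half-sample node positions (j - 1/2) ds, j = 1..K."""
        return (np.arange(self.n_compartments) + 0.5) * self.delta_s

    def kappa(self, m) -> np.ndarray | float:
        """Wavenumber(s) kappa_m = m pi / L of the Neumann cosine modes."""
        return np.asarray(m) * np.pi / self.length


def steady_state(
    network: ReactionNetwork,
    params: Mapping[str, float],
    *,
    n_starts: int = 50,
    seed: int = 0,
    tol: float = 1e-9,
    log_bounds: tuple[float, float] = (-3.0, 3.0),
) -> np.ndarray:
    """Unique positive root of the mass-action right-hand side.

    Multi-start root finding (hybrid Powell with the analytic Jacobian)
    from log-uniform positive starts; roots are merged at relative
    tolerance 1e-6.  Injectivity guarantees at most one positive root, so
    finding two distinct ones signals a modelling error.
    """
    rng = np.random.default_rng(seed)
    n = network.n
    roots: list[np.ndarray] = []

    def fun(x):
        xc = np.clip(x, 0.0, None)  # positivity projection
        return mass_action_rhs(network, params, xc)

    def jac(x):
        xc = np.clip(x, 0.0, None)
        return mass_action_jacobian(network, params, xc)

    for _ in range(n_starts):
        x0 = 10.0 ** rng.uniform(*log_bounds, size=n)
        sol = root(fun, x0, jac=jac, method="hybr")
        x = sol.x
        if not sol.success or np.any(x <= 0):
            continue
        if np.linalg.norm(mass_action_rhs(network, params, x)) > tol * (
            1.0 + np.linalg.norm(x)
        ):
            continue
        if not any(np.allclose(x, r, rtol=1e-6) for r in roots):
            roots.append(x)
    if not roots:
        raise RuntimeError("no positive steady state found within iteration budget")
    if len(roots) > 1:
        raise RuntimeError(
            f"multiple positive roots found ({len(roots)}); network is not monostationary"
        )
    return roots[0]


def jacobian(
    network: ReactionNetwork, params: Mapping[str, float], xstar: np.ndarray
) -> np.ndarray:
    """Analytic Jacobian of the reaction kinetics at the steady state."""
    xstar = np.asarray(xstar, dtype=float)
    if np.any(xstar <= 0):
        raise ValueError("steady state must be strictly positive")
    return mass_action_jacobian(network, params, xstar)


def laplacian_matrix(K: int) -> np.ndarray:
    """Unscaled K x K reflecting-boundary Laplacian stencil.

    Interior rows (1, -2, 1); boundary diagonal -1 (ghost-point Neumann),
    which makes the half-sample cosine vectors exact eigenvectors with
    eigenvalues 2 (cos(m pi / K) - 1).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    lap = np.zeros((K, K))
    if K == 1:
        return lap
    idx = np.arange(K)
    lap[idx, idx] = -2.0
    lap[idx[:-1], idx[:-1] + 1] = 1.0
    lap[idx[1:], idx[1:] - 1] = 1.0
    lap[0, 0] = -1.0
    lap[-1, -1] = -1.0
    return lap


def assemble_A(J: np.ndarray, D: np.ndarray, grid: SpatialGrid) -> np.ndarray:
    """Full nK x nK compartmental operator, species-major block layout."""
    J = np.asarray(J, dtype=float)
    D = np.asarray(D, dtype=float).ravel()
    n = J.shape[0]
    if J.shape != (n, n) or D.shape != (n,):
        raise ValueError("inconsistent J / D dimensions")
    K = grid.n_compartments
    lap = laplacian_matrix(K) / grid.delta_s**2
    A = np.kron(J, np.eye(K))
    for a in range(n):
        A[a * K : (a + 1) * K, a * K : (a + 1) * K] += D[a] * lap
    return A


def mode_matrix(J: np.ndarray, D: np.ndarray, grid: SpatialGrid, m: int) -> np.ndarray:
    """n x n dynamics of cosine mode m: J + (2D/ds^2)(cos(kappa ds) - 1)."""
    if m < 0:
        raise ValueError("mode index must be >= 0")
    J = np.asarray(J, dtype=float)
    D = np.asarray(D, dtype=float).ravel()
    theta = grid.kappa(m) * grid.delta_s  # = m pi / K
    return J + np.diag(2.0 * D / grid.delta_s**2 * (np.cos(theta) - 1.0))


def mode_matrices(
    J: np.ndarray, D: np.ndarray, grid: SpatialGrid, modes: Sequence[int]
) -> np.ndarray:
    return np.stack([mode_matrix(J, D, grid, int(m)) for m in modes])


def max_mode_growth_rate(
    J: np.ndarray, D: np.ndarray, grid: SpatialGrid, modes: Sequence[int] | None = None
) -> float:
    """Largest real part over the eigenvalues of all requested mode matrices."""
    if modes is None:
        modes = range(grid.n_compartments)
    worst = -np.inf
    for m in modes:
        lam = np.linalg.eigvals(mode_matrix(J, D, grid, int(m)))
        worst = max(worst, float(lam.real.max()))
    return worst


def eigenmodes(A_kappa: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Eigenvalues, eigenvectors and a defectiveness flag for a mode matrix.

    Supports the constant-forcing solution
    dx(t) = sum_i c_i nu_i exp(lambda_i t) - A_kappa^-1 eta: the long-time
    limit of a stable mode under frozen red noise is -A_kappa^-1 eta.
    """
    A_kappa = np.asarray(A_kappa, dtype=float)
    lam, vecs = np.linalg.eig(A_kappa)
    # Jordan flag: eigenvector matrix numerically rank deficient
    defective = (
        np.linalg.matrix_rank(vecs, tol=1e-10 * max(1.0, np.abs(vecs).max()))
        < A_kappa.shape[0]
    )
    return lam, vecs, defective


def omega_grid(T: float, dt: float) -> np.ndarray:
    """Angular frequencies omega_q = 2 pi q / T, q = 0..floor(T/(2 dt)).

    Matches the one-sided temporal transform of a length-T record sampled
    at dt, so analytic and empirical spectra share a grid.
    """
    n_steps = int(round(T / dt))
    return 2.0 * np.pi * np.fft.rfftfreq(n_steps, d=dt)


@dataclass
class SpectrumTable:
    """Power over (species, spatial mode m, angular frequency omega)."""

    species: list[str]
    modes: np.ndarray
    omegas: np.ndarray
    power: np.ndarray  # shape (n_species, n_modes, n_omega)
    kind: str = "analytic"  # "analytic" | "empirical"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.modes = np.asarray(self.modes, dtype=int)
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        expect = (len(self.species), self.modes.size, self.omegas.size)
        if self.power.shape != expect:
            raise ValueError(f"power shape {self.power.shape} != {expect}")

    def same_grid(self, other: "SpectrumTable") -> bool:
        return (
            self.species == other.species
            and np.array_equal(self.modes, other.modes)
            and self.omegas.shape == other.omegas.shape
            and np.allclose(self.omegas, other.omegas)
        )

    def to_frame(self) -> pd.DataFrame:
        s, m, w = np.meshgrid(
            np.arange(len(self.species)), self.modes, self.omegas, indexing="ij"
        )
        return pd.DataFrame(
            {
                "species": np.asarray(self.species)[s.ravel()],
                "m": m.ravel(),
                "omega": w.ravel(),
                "power": self.power.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "analytic") -> "SpectrumTable":
        df = pd.read_csv(path)
        species = list(dict.fromkeys(df["species"]))
        modes = np.sort(df["m"].unique())
        omegas = np.sort(df["omega"].unique())
        power = np.full((len(species), modes.size, omegas.size), np.nan)
        s_idx = {s: i for i, s in enumerate(species)}
        m_idx = {m: i for i, m in enumerate(modes)}
        w_idx = {w: i for i, w in enumerate(omegas)}
        for row in df.itertuples(index=False):
            power[s_idx[row.species], m_idx[row.m], w_idx[row.omega]] = row.power
        return cls(species, modes, omegas, power, kind=kind)


def analytic_spectrum(
    J: np.ndarray,
    D: np.ndarray,
    grid: SpatialGrid,
    noise_spectrum: Callable[[np.ndarray], np.ndarray],
    omegas: np.ndarray,
    modes: Sequence[int] | None = None,
    species: Sequence[str] | None = None,
    *,
    check_stability: bool = True,
    stability_tol: float = -1e-12,
    meta: dict | None = None,
) -> SpectrumTable:
    """Predicted power spectra P(m, omega) for every requested mode.

    *noise_spectrum* maps an omega array (W,) to the Hermitian spectral
    matrices N(omega) of shape (W, n, n) (see ``noise.noise_spectrum_N``).
    Raises :class:`UnstableModeError` when any mode matrix fails the
    Hurwitz test, since the stationary spectrum does not exist there.
    """
    omegas = np.asarray(omegas, dtype=float)
    n = np.asarray(J).shape[0]
    if modes is None:
        modes = np.arange(grid.n_compartments)
    modes = np.asarray(modes, dtype=int)
    if species is None:
        species = [f"x{i + 1}" for i in range(n)]

    N = np.asarray(noise_spectrum(omegas), dtype=complex)
    if N.shape != (omegas.size, n, n):
        raise ValueError("noise_spectrum must return shape (n_omega, n, n)")
    if not np.allclose(N, np.conj(np.swapaxes(N, -1, -2)), atol=1e-12):
        raise ValueError("noise spectral matrix must be Hermitian")

    power = np.empty((n, modes.size, omegas.size))
    eye = np.eye(n)
    for mi, m in enumerate(modes):
        Ak = mode_matrix(J, D, grid, int(m))
        if check_stability:
            lam = np.linalg.eigvals(Ak)
            if lam.real.max() >= stability_tol:
                raise UnstableModeError(
                    f"unstable mode m={m}: max Re(lambda) = {lam.real.max():.3e}; "
                    "parameters lie in the Turing/unstable regime"
                )
        phi = -(Ak[None, :, :] + 1j * omegas[:, None, None] * eye)
        phi_inv = np.linalg.inv(phi)
        P = phi_inv @ N @ np.conj(np.swapaxes(phi_inv, -1, -2))
        diag = np.diagonal(P, axis1=-2, axis2=-1)  # (W, n)
        scale = np.abs(diag).max() if diag.size else 1.0
        if scale > 0 and np.abs(diag.imag).max() > 1e-10 * scale:
            raise RuntimeError("spectrum diagonal has non-negligible imaginary part")
        power[:, mi, :] = diag.real.T
    return SpectrumTable(
        list(species), modes, omegas, power, kind="analytic", meta=meta or {}
    )


@dataclass
class LinearizedSystem:
    """Bundle of steady state, Jacobian, diffusion and grid, with the
    compartmental operator and per-mode matrices derived on demand."""

    network: ReactionNetwork
    params: dict
    xstar: np.ndarray
    J: np.ndarray
    D: np.ndarray
    grid: SpatialGrid

    @property
    def A(self) -> np.ndarray:
        return assemble_A(self.J, self.D, self.grid)

    def mode_matrix(self, m: int) -> np.ndarray:
        return mode_matrix(self.J, self.D, self.grid, m)

    def max_growth_rate(self, modes=None) -> float:
        return max_mode_growth_rate(self.J, self.D, self.grid, modes)

    @property
    def coefficients(self) -> dict[str, float]:
        """Interior-row scalar entries of the two-species block operator
        (a0/a1: species-1 diffusion-reaction diagonal and off-diagonal,
        b0/c0: cross couplings, d0/d1: species 2)."""
        if self.J.shape != (2, 2):
            raise ValueError("scalar coefficient names are defined for n = 2 only")
        ds2 = self.grid.delta_s**2
        return {
            "a0": self.J[0, 0] - 2 * self.D[0] / ds2,
            "a1": self.D[0] / ds2,
            "b0": self.J[0, 1],
            "c0": self.J[1, 0],
            "d0": self.J[1, 1] - 2 * self.D[1] / ds2,
            "d1": self.D[1] / ds2,
        }


def linearize(
    network: ReactionNetwork,
    params: Mapping[str, float],
    D: np.ndarray,
    grid: SpatialGrid,
    xstar: np.ndarray | None = None,
    **solver_kwargs,
) -> LinearizedSystem:
    """Compute (or accept) the steady state and build the linearised system."""
    if xstar is None:
        xstar = steady_state(network, params, **solver_kwargs)
    xstar = np.asarray(xstar, dtype=float)
    resid = mass_action_rhs(network, params, xstar)
    if np.linalg.norm(resid) > 1e-6 * (1.0 + np.linalg.norm(xstar)):
        raise ValueError("provided steady state does not satisfy f(x*) = 0")
    J = jacobian(network, params, xstar)
    return LinearizedSystem(
        network=network,
        params=dict(params),
        xstar=xstar,
        J=J,
        D=np.asarray(D, dtype=float).ravel(),
        grid=grid,
    )
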