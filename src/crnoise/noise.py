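"""Noise colours: analytic spectral matrices and time-domain samplers.

The stochastic inflow perturbation eta(t) is a zero-mean Gaussian process,
independent between compartments, with species covariance B and a temporal
correlation g(t - t') named by its colour:

==================  =======================================================
white               g = delta(t-t'),       P_corr(omega) = 1
ornstein_uhlenbeck  g = e^(-|dt|/tau)/2tau, P_corr = 1/(1 + omega^2 tau^2)
power_law           P_corr = 1/|omega|^alpha (red: alpha=2, violet: -2)
auxiliary           quasi-cycle spectrum of a predator-prey subnetwork
mixed               per-species OU correlation times (tau_i = 0 -> white)
==================  =======================================================

Any variant can additionally be *reduced* by a per-species mask (species
without a stochastic inflow get identically zero noise), and *truncated*
so the physical inflow rate K = k + eta/sqrt(Omega) stays non-negative.

Samplers return eta records of shape (n_steps, n_species, n_sites) in rate
units; a simulated Euler-Maruyama step adds eta * dt (white records are
internally scaled so that eta * dt equals the Ito increment b z sqrt(dt)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = [
    "AuxiliarySpectrumParams",
    "NoiseModel",
    "correlation_factor",
    "noise_spectrum_N",
    "factor_covariance",
    "sample_white",
    "sample_ou",
    "sample_mixed",
    "sample_power_law",
    "sample_auxiliary",
    "sample_noise",
    "apply_truncation",
]

VARIANTS = ("white", "ornstein_uhlenbeck", "power_law", "auxiliary", "mixed")

#: accepted aliases for config files / CLI flags
VARIANT_ALIASES = {
    "white": "white",
    "ou": "ornstein_uhlenbeck",
    "ornstein_uhlenbeck": "ornstein_uhlenbeck",
    "power": "power_law",
    "power_law": "power_law",
    "red": "power_law",
    "aux": "auxiliary",
    "auxiliary": "auxiliary",
    "mixed": "mixed",
}


@dataclass(frozen=True)
class AuxiliarySpectrumParams:
    """Coefficients of the predator-prey quasi-cycle input spectrum.

    The spectrum (alpha + beta omega^2) / ((omega^2 - omega0_sq)^2 +
    gamma^2 omega^2) is the standard quasi-cycle form with an interior
    resonance; ``squared_denominator=False`` selects the monotone variant
    (omega^2 + omega0_sq) + gamma^2 omega^2 instead.
    """

    alpha: float
    beta: float
    gamma: float
    omega0_sq: float
    squared_denominator: bool = True

    def __post_init__(self):
        if min(self.alpha, self.beta, self.omega0_sq) < 0 or self.gamma <= 0:
            raise ValueError("need alpha, beta, omega0_sq >= 0 and gamma > 0")

    def spectrum(self, omega) -> np.ndarray:
        w2 = np.asarray(omega, dtype=float) ** 2
        num = self.alpha + self.beta * w2
        if self.squared_denominator:
            den = (w2 - self.omega0_sq) ** 2 + self.gamma**2 * w2
        else:
            den = (w2 + self.omega0_sq) + self.gamma**2 * w2
        return num / den


@dataclass(frozen=True)
class NoiseModel:
    """Full specification of the stochastic inflow forcing."""

    covariance: np.ndarray  # species covariance B, n x n PSD
    variant: str = "white"
    tau: float | None = None  # ornstein_uhlenbeck
    alpha: float | None = None  # power_law exponent
    aux: AuxiliarySpectrumParams | None = None
    taus: tuple[float, ...] | None = None  # mixed: per-species, 0 -> white
    mask: tuple[bool, ...] | None = None  # reduced inflows
    omega_strength: float = 100.0  # subsystem size Omega
    truncate: bool = False

    def __post_init__(self):
        B = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        object.__setattr__(self, "covariance", B)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValueError("covariance must be a square matrix")
        if not np.allclose(B, B.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(B).min() < -1e-8 * max(1.0, np.abs(B).max()):
            raise ValueError("covariance must be positive semi-definite")
        variant = VARIANT_ALIASES.get(self.variant)
        if variant is None:
            raise ValueError(f"unknown noise variant {self.variant!r}")
        object.__setattr__(self, "variant", variant)
        if variant == "ornstein_uhlenbeck" and (self.tau is None or self.tau <= 0):
            raise ValueError("ornstein_uhlenbeck requires tau > 0")
        if variant == "power_law" and self.alpha is None:
            raise ValueError("power_law requires an exponent alpha")
        if variant == "auxiliary" and self.aux is None:
            raise ValueError("auxiliary requires AuxiliarySpectrumParams")
        if variant == "mixed":
            if self.taus is None or len(self.taus) != B.shape[0]:
                raise ValueError("mixed requires one tau per species (0 means white)")
            if any(t < 0 for t in self.taus):
                raise ValueError("mixed correlation times must be >= 0")
            object.__setattr__(self, "taus", tuple(float(t) for t in self.taus))
        if self.mask is not None:
            if len(self.mask) != B.shape[0]:
                raise ValueError("mask length must equal the number of species")
            object.__setattr__(self, "mask", tuple(bool(m) for m in self.mask))
        if self.omega_strength <= 0:
            raise ValueError("noise strength Omega must be positive")

    @property
    def n(self) -> int:
        return self.covariance.shape[0]

    def with_mask(self, mask) -> "NoiseModel":
        return replace(self, mask=tuple(bool(m) for m in mask))

    def describe(self) -> dict:
        out = {
            "variant": self.variant,
            "Omega": self.omega_strength,
            "truncate": self.truncate,
            "B": self.covariance.tolist(),
        }
        if self.tau is not None:
            out["tau"] = self.tau
        if self.alpha is not None:
            out["alpha"] = self.alpha
        if self.taus is not None:
            out["taus"] = list(self.taus)
        if self.aux is not None:
            out["aux"] = {
                "alpha": self.aux.alpha,
                "beta": self.aux.beta,
                "gamma": self.aux.gamma,
                "omega0_sq": self.aux.omega0_sq,
                "squared_denominator": self.aux.squared_denominator,
            }
        if self.mask is not None:
            out["mask"] = list(self.mask)
        return out


# ---------------------------------------------------------------------------
# analytic spectra
# ---------------------------------------------------------------------------

def correlation_factor(model: NoiseModel, omega) -> np.ndarray:
    """Scalar spectral factor P_Correlations(omega) of the noise colour.

    Defined for the common-correlation variants; the mixed variant has no
    scalar factor (its spectral matrix is built in noise_spectrum_N).
    """
    omega = np.asarray(omega, dtype=float)
    if model.variant == "white":
        return np.ones_like(omega)
    if model.variant == "ornstein_uhlenbeck":
        return 1.0 / (1.0 + omega**2 * model.tau**2)
    if model.variant == "power_law":
        if model.alpha > 0 and np.any(omega == 0.0):
            raise ValueError(
                "power-law spectrum diverges at omega = 0; exclude it from the grid"
            )
        with np.errstate(divide="ignore"):
            return np.abs(omega) ** (-model.alpha)
    if model.variant == "auxiliary":
        return model.aux.spectrum(omega)
    raise ValueError(f"no scalar correlation factor for variant {model.variant!r}")


def _mask_matrix(model: NoiseModel) -> np.ndarray:
    if model.mask is None:
        return np.eye(model.n)
    return np.diag(np.asarray(model.mask, dtype=float))


def noise_spectrum_N(model: NoiseModel, omega) -> np.ndarray:
    """Hermitian spectral matrix N(omega), shape (..., n, n).

    Common-correlation colours factorise as B * P_corr(omega); the mixed
    variant filters the shared white source through per-species first-order
    transfer functions H_i = 1/(1 + i omega tau_i), giving
    N = diag(H) B diag(H)^dagger.  A reduced mask zeroes the rows and
    columns of masked-off species for every colour.
    """
    omega = np.asarray(omega, dtype=float)
    scalar_input = omega.ndim == 0
    omega = np.atleast_1d(omega)
    Bm = _mask_matrix(model) @ model.covariance @ _mask_matrix(model)
    if model.variant == "mixed":
        taus = np.asarray(model.taus, dtype=float)
        H = 1.0 / (1.0 + 1j * omega[:, None] * taus[None, :])  # (W, n)
        N = H[:, :, None] * Bm[None, :, :] * np.conj(H)[:, None, :]
    else:
        factor = correlation_factor(model, omega)
        N = Bm[None, :, :] * factor[:, None, None].astype(complex)
    return N[0] if scalar_input else N


def factor_covariance(B: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Symmetric square root b with b b^T = B (eigen-decomposition).

    Eigenvalues in [-1e-12, 0) are clipped to zero; anything below -tol
    (relative) is rejected as genuinely indefinite.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    lam, V = np.linalg.eigh(B)
    scale = max(1.0, np.abs(lam).max())
    if lam.min() < -tol * scale:
        raise ValueError(f"covariance has negative eigenvalue {lam.min():.3e}")
    lam = np.clip(lam, 0.0, None)
    return (V * np.sqrt(lam)) @ V.T


# ---------------------------------------------------------------------------
# time-domain samplers
# ---------------------------------------------------------------------------

def sample_white(
    n_steps: int, dt: float, b: np.ndarray, rng: np.random.Generator, n_sites: int = 1
) -> np.ndarray:
    """White-noise record: eta = b z / sqrt(dt), so eta*dt = b z sqrt(dt)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    b = np.atleast_2d(b)
    z = rng.standard_normal((n_steps, b.shape[1], n_sites))
    return np.einsum("ij,tjs->tis", b, z) / np.sqrt(dt)


def sample_mixed(
    taus,
    n_steps: int,
    dt: float,
    b: np.ndarray,
    rng: np.random.Generator,
    n_sites: int = 1,
) -> np.ndarray:
    """Per-species Ornstein-Uhlenbeck filtering of a shared white source.

    Species i integrates d eta_i = -eta_i/tau_i dt + (b dW)_i / tau_i from
    its stationary distribution; tau_i = 0 passes the white source through
    unfiltered.  Cross-correlations come from the common mixing b.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    b = np.atleast_2d(b)
    taus = np.asarray(taus, dtype=float)
    n = b.shape[0]
    if taus.shape != (n,):
        raise ValueError("need one correlation time per species")
    coloured = taus > 0
    if np.any(taus[coloured] <= dt):
        raise ValueError("correlation times must exceed the time step dt")

    out = np.empty((n_steps, n, n_sites))
    # stationary initial condition for the filtered channels
    eta = np.einsum("ij,js->is", b, rng.standard_normal((b.shape[1], n_sites)))
    eta[coloured] /= np.sqrt(2.0 * taus[coloured, None])
    decay = np.where(coloured, 1.0 - dt / np.where(coloured, taus, 1.0), 0.0)
    for t in range(n_steps):
        dW = np.einsum("ij,js->is", b, rng.standard_normal((b.shape[1], n_sites)))
        dW *= np.sqrt(dt)
        drive = np.where(coloured[:, None], dW / np.where(coloured, taus, 1.0)[:, None],
                         dW / dt)
        eta = decay[:, None] * eta + drive
        out[t] = eta
    return out


def sample_ou(
    tau: float,
    n_steps: int,
    dt: float,
    b: np.ndarray,
    rng: np.random.Generator,
    n_sites: int = 1,
) -> np.ndarray:
    """Common-correlation-time Ornstein-Uhlenbeck record.

    Stationary variance B_ii/(2 tau) per species and autocorrelation
    exp(-|t - t'|/tau), i.e. the Lorentzian colour 1/(1 + omega^2 tau^2).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    b = np.atleast_2d(b)
    return sample_mixed(np.full(b.shape[0], tau), n_steps, dt, b, rng, n_sites)


def _synthesize_from_spectrum(
    target: np.ndarray, n_steps: int, dt: float, rng: np.random.Generator, channels: tuple
) -> np.ndarray:
    """Gaussian series with one-sided spectral density *target* (per rfft bin).

    Frequency-domain (inverse-transform) synthesis: independent complex
    Gaussian amplitudes with E|X_q|^2 = n_steps * S(omega_q) / dt, Hermitian
    symmetry implied by irfft, zero-frequency amplitude pinned to 0 (the
    noise is zero-mean by construction).
    """
    n_freq = n_steps // 2 + 1
    if target.shape != (n_freq,):
        raise ValueError("target spectrum must be evaluated on the rfft grid")
    shape = (*channels, n_freq)
    scale = np.sqrt(n_steps * target / dt / 2.0)
    X = scale * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    X[..., 0] = 0.0
    if n_steps % 2 == 0:  # real Nyquist bin carries no phase partner
        X[..., -1] = np.sqrt(n_steps * target[-1] / dt) * rng.standard_normal(channels)
    x = np.fft.irfft(X, n=n_steps, axis=-1)
    return np.moveaxis(x, -1, 0)  # (n_steps, *channels)


def sample_power_law(
    alpha: float,
    n_steps: int,
    dt: float,
    b: np.ndarray,
    rng: np.random.Generator,
    n_sites: int = 1,
) -> np.ndarray:
    """Power-law (1/omega^alpha) record via frequency-domain synthesis.

    Normalised so that alpha = 0 reproduces white-noise statistics (up to
    the enforced zero record mean); species are mixed through b after
    synthesising independent unit channels.
    """
    omega = 2.0 * np.pi * np.fft.rfftfreq(n_steps, d=dt)
    target = np.empty_like(omega)
    target[0] = 0.0  # pinned below anyway; avoids 0**-alpha warnings
    target[1:] = omega[1:] ** (-alpha)
    b = np.atleast_2d(b)
    xi = _synthesize_from_spectrum(target, n_steps, dt, rng, (b.shape[1], n_sites))
    return np.einsum("ij,tjs->tis", b, xi)


def sample_auxiliary(
    params: AuxiliarySpectrumParams,
    n_steps: int,
    dt: float,
    b: np.ndarray,
    rng: np.random.Generator,
    n_sites: int = 1,
) -> np.ndarray:
    """Quasi-cycle (auxiliary predator-prey network) noise record.

    Same inverse-transform synthesis as the power-law sampler, with the
    quasi-cycle input spectrum as target.
    """
    omega = 2.0 * np.pi * np.fft.rfftfreq(n_steps, d=dt)
    target = params.spectrum(omega)
    b = np.atleast_2d(b)
    xi = _synthesize_from_spectrum(target, n_steps, dt, rng, (b.shape[1], n_sites))
    return np.einsum("ij,tjs->tis", b, xi)


def sample_noise(
    model: NoiseModel,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
    n_sites: int = 1,
) -> np.ndarray:
    """Dispatch to the variant's sampler and apply the reduced-inflow mask."""
    b = factor_covariance(model.covariance)
    if model.variant == "white":
        record = sample_white(n_steps, dt, b, rng, n_sites)
    elif model.variant == "ornstein_uhlenbeck":
        record = sample_ou(model.tau, n_steps, dt, b, rng, n_sites)
    elif model.variant == "mixed":
        record = sample_mixed(model.taus, n_steps, dt, b, rng, n_sites)
    elif model.variant == "power_law":
        record = sample_power_law(model.alpha, n_steps, dt, b, rng, n_sites)
    elif model.variant == "auxiliary":
        record = sample_auxiliary(model.aux, n_steps, dt, b, rng, n_sites)
    else:  # pragma: no cover - guarded by NoiseModel validation
        raise ValueError(model.variant)
    if model.mask is not None:
        record = record * np.asarray(model.mask, dtype=float)[None, :, None]
    return record


def apply_truncation(
    record: np.ndarray, inflow_rates: np.ndarray, omega_strength: float
) -> tuple[np.ndarray, float]:
    """Clamp eta so the physical inflow K = k + eta/sqrt(Omega) stays >= 0.

    Equivalently eta_i >= -k_i sqrt(Omega).  Returns the clamped record and
    the fraction of samples that were clamped (a diagnostic: the analytic
    theory assumes this fraction is negligible).
    """
    if omega_strength <= 0:
        raise ValueError("Omega must be positive")
    k = np.asarray(inflow_rates, dtype=float)
    thresh = -k * np.sqrt(omega_strength)
    low = record < thresh[None, :, None]
    frac = float(low.mean())
    return np.maximum(record, thresh[None, :, None]), frac


def noise_model_from_config(block: Mapping, n_species: int) -> NoiseModel:
    """Build a NoiseModel from a config-file noise block (see cli docs)."""
    colour = VARIANT_ALIASES.get(str(block.get("colour", "white")).lower())
    if colour is None:
        raise ValueError(f"unknown noise colour {block.get('colour')!r}")
    B = np.asarray(block.get("B", np.ones((n_species, n_species))), dtype=float)
    aux = None
    if "aux" in block and block["aux"] is not None:
        a = block["aux"]
        aux = AuxiliarySpectrumParams(
            alpha=float(a["alpha"]),
            beta=float(a["beta"]),
            gamma=float(a["gamma"]),
            omega0_sq=float(a["omega0sq"]),
            squared_denominator=bool(a.get("squared_denominator", True)),
        )
    return NoiseModel(
        covariance=B,
        variant=colour,
        tau=block.get("tau"),
        alpha=block.get("alpha"),
        aux=aux,
        taus=tuple(block["taus"]) if "taus" in block and block["taus"] else None,
        mask=tuple(block["mask"]) if "mask" in block and block["mask"] else None,
        omega_strength=float(block.get("Omega", 100.0)),
        truncate=bool(block.get("truncate", False)),
    )
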