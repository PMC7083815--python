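"""Worked-example systems: the Schnakenberg activator-depleted-substrate
model and the predator-prey quasi-cycle input spectrum."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crn import Reaction, ReactionNetwork
from .linear_model import SpatialGrid
from .noise import AuxiliarySpectrumParams

__all__ = [
    "schnakenberg_network",
    "schnakenberg_parameters",
    "schnakenberg_steady_state",
    "schnakenberg_preset",
    "SchnakenbergPreset",
    "predator_prey_network",
    "predator_prey_preset",
    "default_covariance",
]


def schnakenberg_network() -> ReactionNetwork:
    """The four-reaction Schnakenberg scheme.

    0 -> X1 (k1), X1 -> 0 (k-1), 0 -> X2 (k2), 2X1 + X2 -> 3X1 (k3);
    reaction order fixes the column layout of the stoichiometric matrix.
    """
    return ReactionNetwork(
        species=["X1", "X2"],
        reactions=[
            Reaction.make({}, {"X1": 1}, "k1"),
            Reaction.make({"X1": 1}, {}, "k-1"),
            Reaction.make({}, {"X2": 1}, "k2"),
            Reaction.make({"X1": 2, "X2": 1}, {"X1": 3}, "k3"),
        ],
    )


def schnakenberg_parameters() -> dict[str, float]:
    """Reference rate constants: stable oscillatory regime, outside the
    Turing space, with large inflows relative to the cubic reaction."""
    return {"k1": 10.0, "k2": 10.0, "k3": 0.01, "k-1": 20.0}


def schnakenberg_steady_state(params: dict[str, float]) -> np.ndarray:
    """Closed-form unique positive steady state.

    x1* = (k1 + k2)/k-1,  x2* = k2 k-1^2 / (k3 (k1 + k2)^2).
    """
    k1, k2, k3, km1 = params["k1"], params["k2"], params["k3"], params["k-1"]
    x1 = (k1 + k2) / km1
    x2 = k2 * km1**2 / (k3 * (k1 + k2) ** 2)
    return np.array([x1, x2])


@dataclass(frozen=True)
class SchnakenbergPreset:
    network: ReactionNetwork
    params: dict
    diffusion: np.ndarray
    grid: SpatialGrid

    def steady_state(self) -> np.ndarray:
        return schnakenberg_steady_state(self.params)

    def jacobian(self) -> np.ndarray:
        from .linear_model import jacobian

        return jacobian(self.network, self.params, self.steady_state())


def schnakenberg_preset() -> SchnakenbergPreset:
    """Reference configuration: k1 = k2 = 10, k3 = 0.01, k-1 = 20,
    D = (1e-4, 1e-2), L = 0.1 split into K = 40 compartments."""
    return SchnakenbergPreset(
        network=schnakenberg_network(),
        params=schnakenberg_parameters(),
        diffusion=np.array([1e-4, 1e-2]),
        grid=SpatialGrid(length=0.1, n_compartments=40),
    )


def predator_prey_network() -> ReactionNetwork:
    """Auxiliary predator-prey network (death of each species, predation
    converting prey to predator, and a second predation channel)."""
    return ReactionNetwork(
        species=["Y1", "Y2"],
        reactions=[
            Reaction.make({"Y1": 1}, {}, "d1"),
            Reaction.make({"Y2": 1}, {}, "d2"),
            Reaction.make({"Y1": 1, "Y2": 1}, {"Y1": 2}, "p1"),
            Reaction.make({"Y1": 1, "Y2": 1}, {"Y1": 1}, "p2"),
        ],
    )


def predator_prey_preset() -> AuxiliarySpectrumParams:
    """Quasi-cycle input-spectrum coefficients of the reference
    predator-prey subnetwork (squared-denominator resonant form)."""
    return AuxiliarySpectrumParams(
        alpha=0.000384, beta=0.04, gamma=0.04, omega0_sq=0.016
    )


def default_covariance(n: int = 2) -> np.ndarray:
    """Fully correlated unit species covariance (rank one, all ones)."""
    return np.ones((n, n))
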