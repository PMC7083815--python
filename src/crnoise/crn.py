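"""Mass-action chemical reaction networks and structural monostationarity.

A reaction network is a list of reactions ``sum_i alpha_i X_i -> sum_i
beta_i X_i`` over named species.  Two integer matrices encode its
structure: the stoichiometric matrix ``m1`` (columns are the reaction
vectors ``beta - alpha``) and the reactant-complex matrix ``m2`` (rows are
the reactant stoichiometries ``alpha``).  Under mass-action kinetics the
concentration dynamics are

    dx/dt = f(x) = m1 @ diag(k) @ x**m2,

with ``x**m2`` the vector of reactant monomials.

The network is *monostationary for every positive rate vector* -- so
stochastic parameter drift can never trigger switching between steady
states -- whenever ``f`` is injective, which holds if

    ker(m2) = {0}   and   sigma(ker(m1)) & sigma(im(m2)) = {0},

where ``sigma`` maps a vector to its componentwise sign pattern in
{-,0,+}.  :func:`check_injectivity` decides this exactly by enumerating
sign patterns and testing membership in each sign-vector set with a
linear-programming feasibility problem.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "InjectivityReport",
    "build_stoichiometry",
    "mass_action_rhs",
    "mass_action_jacobian",
    "inflow_rates",
    "sign_vector",
    "format_sign_pattern",
    "check_injectivity",
]

#: absolute tolerance below which a floating-point component counts as zero
SIGN_ZERO_TOL = 1e-9


@dataclass(frozen=True)
class Reaction:
    """A single irreversible reaction with integer stoichiometries.

    Reversible reactions are encoded as two Reaction objects.  The empty
    complex (inflow/outflow) is simply an empty mapping.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: str

    @classmethod
    def make(
        cls,
        reactants: Mapping[str, int],
        products: Mapping[str, int],
        rate: str,
    ) -> "Reaction":
        return cls(
            tuple(sorted(reactants.items())),
            tuple(sorted(products.items())),
            rate,
        )

    def reactant_dict(self) -> dict[str, int]:
        return dict(self.reactants)

    def product_dict(self) -> dict[str, int]:
        return dict(self.products)


class ReactionNetwork:
    """An ordered collection of species and mass-action reactions.

    Species order is declaration order and fixes the row layout of ``m1``
    and the column layout of ``m2``.
    """

    def __init__(self, species: Sequence[str], reactions: Sequence[Reaction]):
        species = list(species)
        reactions = list(reactions)
        if not species:
            raise ValueError("network needs at least one species")
        if not reactions:
            raise ValueError("network needs at least one reaction")
        if len(set(species)) != len(species):
            raise ValueError("species names must be unique")
        rates = [r.rate for r in reactions]
        if len(set(rates)) != len(rates):
            raise ValueError("each rate name must be attached to exactly one reaction")
        known = set(species)
        for r in reactions:
            for name, coeff in (*r.reactants, *r.products):
                if name not in known:
                    raise ValueError(f"unknown species {name!r} in reaction {r.rate}")
                if not isinstance(coeff, (int, np.integer)) or coeff < 0:
                    raise ValueError(
                        f"stoichiometries must be non-negative integers, got {coeff!r}"
                    )
        self.species = species
        self.reactions = reactions

    # -- derived structure -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of species."""
        return len(self.species)

    @property
    def M(self) -> int:
        """Number of reactions."""
        return len(self.reactions)

    @property
    def rate_names(self) -> list[str]:
        return [r.rate for r in self.reactions]

    def _index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.species)}

    @property
    def m1(self) -> np.ndarray:
        """n x M stoichiometric matrix; column i is beta_i - alpha_i."""
        idx = self._index()
        out = np.zeros((self.n, self.M), dtype=int)
        for j, r in enumerate(self.reactions):
            for name, c in r.products:
                out[idx[name], j] += c
            for name, c in r.reactants:
                out[idx[name], j] -= c
        return out

    @property
    def m2(self) -> np.ndarray:
        """M x n reactant-complex matrix; row i is alpha_i."""
        idx = self._index()
        out = np.zeros((self.M, self.n), dtype=int)
        for j, r in enumerate(self.reactions):
            for name, c in r.reactants:
                out[j, idx[name]] = c
        return out

    def rate_vector(self, params: Mapping[str, float]) -> np.ndarray:
        k = np.empty(self.M)
        for j, r in enumerate(self.reactions):
            if r.rate not in params:
                raise KeyError(f"missing rate value for {r.rate!r}")
            val = float(params[r.rate])
            if val <= 0:
                raise ValueError(f"rate constant {r.rate!r} must be positive")
            k[j] = val
        return k

    def permuted(self, order: Sequence[int]) -> "ReactionNetwork":
        """Return the same network with reactions reordered (for testing
        that structural verdicts are order independent)."""
        return ReactionNetwork(self.species, [self.reactions[i] for i in order])

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "reactions": [
                {
                    "reactants": r.reactant_dict(),
                    "products": r.product_dict(),
                    "rate": r.rate,
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ReactionNetwork":
        reactions = [
            Reaction.make(r.get("reactants", {}), r.get("products", {}), r["rate"])
            for r in data["reactions"]
        ]
        return cls(data["species"], reactions)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ReactionNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ReactionNetwork(n={self.n}, M={self.M}, species={self.species})"


def build_stoichiometry(network: ReactionNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(m1, m2)`` for *network* (deterministic in reaction order)."""
    return network.m1, network.m2


def mass_action_rhs(
    network: ReactionNetwork, params: Mapping[str, float], x: np.ndarray
) -> np.ndarray:
    """Evaluate ``f(x) = m1 diag(k) x**m2`` at non-negative concentrations."""
    x = np.asarray(x, dtype=float)
    if x.shape != (network.n,):
        raise ValueError(f"expected concentration vector of length {network.n}")
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    k = network.rate_vector(params)
    monomials = np.prod(x[None, :] ** network.m2, axis=1)  # 0**0 == 1
    return network.m1 @ (k * monomials)


def mass_action_jacobian(
    network: ReactionNetwork, params: Mapping[str, float], x: np.ndarray
) -> np.ndarray:
    """Exact Jacobian of the mass-action right-hand side.

    Differentiates each monomial analytically:
    d/dx_j [k x^alpha] = k alpha_j x^(alpha - e_j), assembled through m1.
    Valid for any x >= 0 (terms with alpha_j = 0 vanish identically).
    """
    x = np.asarray(x, dtype=float)
    k = network.rate_vector(params)
    m1, m2 = network.m1, network.m2
    n, M = network.n, network.M
    grad = np.zeros((M, n))  # grad[i, j] = d(x^alpha_i)/dx_j
    for i in range(M):
        alpha = m2[i]
        for j in range(n):
            if alpha[j] == 0:
                continue
            expo = alpha.copy()
            expo[j] -= 1
            grad[i, j] = alpha[j] * np.prod(x ** expo)
    return m1 @ (k[:, None] * grad)


def inflow_rates(network: ReactionNetwork, params: Mapping[str, float]) -> np.ndarray:
    """Per-species deterministic inflow rate: contributions of reactions with
    the empty reactant complex (the physically fluctuating rates)."""
    k = network.rate_vector(params)
    out = np.zeros(network.n)
    idx = network._index()
    for j, r in enumerate(network.reactions):
        if not r.reactants:  # zero complex
            for name, c in r.products:
                out[idx[name]] += c * k[j]
    return out


# ---------------------------------------------------------------------------
# sign vectors and the injectivity decision
# ---------------------------------------------------------------------------

def sign_vector(v: np.ndarray, tol: float = SIGN_ZERO_TOL) -> np.ndarray:
    """Componentwise sign pattern of *v* as an int8 array over {-1, 0, +1}.

    Integer input is signed exactly; floating input uses the absolute zero
    tolerance *tol* so that round-off does not masquerade as structure.
    """
    v = np.asarray(v)
    if np.issubdtype(v.dtype, np.integer):
        return np.sign(v).astype(np.int8)
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("sign_vector requires finite entries")
    out = np.zeros(v.shape, dtype=np.int8)
    out[v > tol] = 1
    out[v < -tol] = -1
    return out


def format_sign_pattern(sigma: Iterable[int]) -> str:
    """Render e.g. (1, 1, 0, -1) as ``(+,+,0,-)``."""
    symbols = {1: "+", 0: "0", -1: "-"}
    return "(" + ",".join(symbols[int(s)] for s in sigma) + ")"


def _kernel_member(m1: np.ndarray, sigma: Sequence[int]) -> np.ndarray | None:
    """A vector v with m1 v = 0 and sign(v) = sigma, or None.

    Sign sets of subspaces are closed under positive scaling, so the strict
    inequalities sign(v_i) = +/- relax exactly to v_i >= 1 / v_i <= -1.
    """
    M = m1.shape[1]
    bounds = []
    for s in sigma:
        if s > 0:
            bounds.append((1.0, None))
        elif s < 0:
            bounds.append((None, -1.0))
        else:
            bounds.append((0.0, 0.0))
    res = linprog(
        c=np.zeros(M),
        A_eq=m1.astype(float),
        b_eq=np.zeros(m1.shape[0]),
        bounds=bounds,
        method="highs",
    )
    return res.x if res.status == 0 else None


def _image_member(m2: np.ndarray, sigma: Sequence[int]) -> np.ndarray | None:
    """A vector y with sign(m2 y) = sigma, or None (returns y, not m2 y)."""
    M, n = m2.shape
    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    for i, s in enumerate(sigma):
        row = m2[i].astype(float)
        if s > 0:
            A_ub.append(-row)
            b_ub.append(-1.0)
        elif s < 0:
            A_ub.append(row)
            b_ub.append(-1.0)
        else:
            A_eq.append(row)
            b_eq.append(0.0)
    res = linprog(
        c=np.zeros(n),
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=[(None, None)] * n,
        method="highs",
    )
    return res.x if res.status == 0 else None


@dataclass
class InjectivityReport:
    """Outcome of the structural monostationarity test.

    ``injective`` is the conjunction of the two conditions.  When the
    sign-set intersection is non-trivial, ``witness`` holds a pair
    ``(v, w)`` with ``v in ker(m1)``, ``w in im(m2)`` and equal non-zero
    sign pattern.  ``ker_sign_patterns`` / ``im_sign_patterns`` list the
    non-zero sign patterns found to be members of each set (closed under
    negation; both orientations are included).
    """

    ker_m2_trivial: bool
    sign_intersection_trivial: bool
    witness: tuple[np.ndarray, np.ndarray] | None = None
    ker_sign_patterns: list[tuple[int, ...]] = field(default_factory=list)
    im_sign_patterns: list[tuple[int, ...]] = field(default_factory=list)

    @property
    def injective(self) -> bool:
        return self.ker_m2_trivial and self.sign_intersection_trivial

    def to_dict(self) -> dict:
        return {
            "injective": self.injective,
            "ker_m2_trivial": self.ker_m2_trivial,
            "sign_intersection_trivial": self.sign_intersection_trivial,
            "witness": None
            if self.witness is None
            else [self.witness[0].tolist(), self.witness[1].tolist()],
            "ker_sign_patterns": [format_sign_pattern(s) for s in self.ker_sign_patterns],
            "im_sign_patterns": [format_sign_pattern(s) for s in self.im_sign_patterns],
        }

    def summary(self) -> str:
        lines = [
            f"ker(m2) trivial:            {self.ker_m2_trivial}",
            f"sign intersection trivial:  {self.sign_intersection_trivial}",
            f"injective (monostationary): {self.injective}",
        ]
        if self.ker_sign_patterns:
            lines.append(
                "sign patterns of ker(m1): "
                + " ".join(format_sign_pattern(s) for s in self.ker_sign_patterns)
            )
        if self.im_sign_patterns:
            lines.append(
                "sign patterns of im(m2):  "
                + " ".join(format_sign_pattern(s) for s in self.im_sign_patterns)
            )
        if self.witness is not None:
            v, w = self.witness
            lines.append(f"witness ker(m1) vector: {np.round(v, 6).tolist()}")
            lines.append(f"witness im(m2) vector:  {np.round(w, 6).tolist()}")
        return "\n".join(lines)


def check_injectivity(
    network: ReactionNetwork,
    max_patterns: int = 60_000,
    collect_patterns: bool = True,
) -> InjectivityReport:
    """Decide monostationarity of *network* for all positive rate constants.

    Enumerates every non-zero sign pattern in {-,0,+}^M up to global sign
    (both sets are subspaces, hence symmetric under negation) and tests
    membership in sigma(ker m1) and sigma(im m2) by LP feasibility.  Exact
    and parameter free, but exponential in the number of reactions M; a
    budget guard refuses networks beyond ``max_patterns`` patterns.
    """
    m1, m2 = network.m1, network.m2
    M, n = network.M, network.n
    if 3**M > max_patterns:
        raise ValueError(
            f"3^{M} sign patterns exceed the enumeration budget of {max_patterns}; "
            "the exact test is desk-scale only"
        )

    ker_m2_trivial = int(np.linalg.matrix_rank(m2)) == n

    ker_patterns: list[tuple[int, ...]] = []
    im_patterns: list[tuple[int, ...]] = []
    witness = None
    intersection_trivial = True

    for sigma in itertools.product((0, 1, -1), repeat=M):
        # canonical orientation: first non-zero entry is +
        nz = next((s for s in sigma if s != 0), 0)
        if nz == 0 or nz < 0:
            continue
        v = _kernel_member(m1, sigma)
        y = _image_member(m2, sigma)
        if v is not None:
            ker_patterns.extend([sigma, tuple(-s for s in sigma)])
        if y is not None:
            im_patterns.extend([sigma, tuple(-s for s in sigma)])
        if v is not None and y is not None:
            intersection_trivial = False
            if witness is None:
                witness = (v, m2.astype(float) @ y)
            if not collect_patterns:
                break

    return InjectivityReport(
        ker_m2_trivial=ker_m2_trivial,
        sign_intersection_trivial=intersection_trivial,
        witness=witness,
        ker_sign_patterns=ker_patterns if collect_patterns else [],
        im_sign_patterns=im_patterns if collect_patterns else [],
    )
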