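"""Pair-potential algebra for ion force fields.

Implements the 12-6(-4) Lennard-Jones pair potential, the Lorentz-Berthelot
combination rules and their scaled variant

    sigma_ij = lambda_sigma * (sigma_i + sigma_j) / 2
    eps_ij   = lambda_eps   * sqrt(eps_i * eps_j)

used to tune ion-ion and ion-biomolecule interactions without touching the
ion-water parameters, plus a registry of the two optimized Mg2+ parameter
sets (*microMg*, exchange on the microsecond timescale; *nanoMg*, exchange on
the nanosecond timescale) for use with TIP3P water.

Units: nm, kJ/mol, elementary charges throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, LookupError_
from .units import COULOMB_CONSTANT

__all__ = [
    "LJParams",
    "IonModel",
    "PairInteraction",
    "ScalingFactors",
    "TIP3P_OXYGEN",
    "AMBER_PHOSPHATE_OXYGEN",
    "lj_energy",
    "coulomb_energy",
    "combine_lb",
    "combine_scaled",
    "invert_lb_sigma",
    "invert_lb_epsilon",
    "builtin_params",
    "available_params",
    "potential_curve",
]


@dataclass(frozen=True)
class LJParams:
    """Lennard-Jones self parameters: diameter ``sigma`` (nm) and well depth
    ``epsilon`` (kJ/mol)."""

    sigma: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DomainError(f"sigma must be positive, got {self.sigma}")
        if self.epsilon < 0:
            raise DomainError(f"epsilon must be nonnegative, got {self.epsilon}")


@dataclass(frozen=True)
class IonModel:
    """A charged species: name, charge in elementary charges, LJ parameters."""

    name: str
    charge: float
    lj: LJParams

    def __post_init__(self) -> None:
        if not self.name:
            raise DomainError("ion model name must be nonempty")


@dataclass(frozen=True)
class PairInteraction:
    """Effective pair parameters between two species.

    ``c4`` is the coefficient of an attractive r^-4 term (kJ nm^4/mol) that
    mimics charge-induced dipole interactions in 12-6-4 models; it is stored
    positive and subtracted.  ``provenance`` records how the pair was formed.
    """

    sigma_ij: float
    epsilon_ij: float
    c4: float = 0.0
    provenance: str = "explicit"

    def __post_init__(self) -> None:
        if self.sigma_ij <= 0:
            raise DomainError(f"sigma_ij must be positive, got {self.sigma_ij}")
        if self.epsilon_ij < 0:
            raise DomainError(f"epsilon_ij must be nonnegative, got {self.epsilon_ij}")
        if self.c4 < 0:
            raise DomainError(f"c4 must be nonnegative, got {self.c4}")


@dataclass(frozen=True)
class ScalingFactors:
    """Multiplicative modifications of the combination rules for one partner
    class (``species_tag`` e.g. ``"Cl"`` or ``"RNA"``)."""

    lambda_sigma: float
    lambda_epsilon: float
    species_tag: str

    def __post_init__(self) -> None:
        if self.lambda_sigma <= 0 or self.lambda_epsilon <= 0:
            raise DomainError("scaling factors must be positive")


#: TIP3P water oxygen LJ parameters (hydrogens carry no LJ site).
TIP3P_OXYGEN = LJParams(sigma=0.315061, epsilon=0.6364)

#: AMBER nonbridging phosphate oxygen (type O2), the dominant inner-sphere
#: Mg2+-binding site on RNA backbones.
AMBER_PHOSPHATE_OXYGEN = LJParams(sigma=0.295992, epsilon=0.87864)


def lj_energy(pair: PairInteraction, r) -> np.ndarray | float:
    """Evaluate the 12-6(-4) pair potential at distance ``r`` (nm).

    V(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 ] - c4 / r^4

    With ``c4 == 0`` this is the plain 12-6 Lennard-Jones form.  Accepts a
    scalar or array ``r``; raises :class:`DomainError` on any r <= 0.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise DomainError("lj_energy requires r > 0")
    x = pair.sigma_ij / r_arr
    x6 = x**6
    v = 4.0 * pair.epsilon_ij * (x6 * x6 - x6) - pair.c4 / r_arr**4
    return v if np.ndim(r) else float(v)


def coulomb_energy(q_i: float, q_j: float, r) -> np.ndarray | float:
    """Coulomb pair energy q_i q_j k_e / r in kJ/mol (charges in e, r in nm)."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise DomainError("coulomb_energy requires r > 0")
    v = COULOMB_CONSTANT * (q_i * q_j) / r_arr
    return v if np.ndim(r) else float(v)


def combine_lb(a: LJParams, b: LJParams) -> PairInteraction:
    """Standard Lorentz-Berthelot rules: arithmetic-mean sigma, geometric-mean
    epsilon."""
    return PairInteraction(
        sigma_ij=0.5 * (a.sigma + b.sigma),
        epsilon_ij=float(np.sqrt(a.epsilon * b.epsilon)),
        provenance="standard-rule",
    )


def combine_scaled(a: LJParams, b: LJParams, s: ScalingFactors) -> PairInteraction:
    """Scaled Lorentz-Berthelot rules with adjustable lambda_sigma and
    lambda_epsilon; reduces to :func:`combine_lb` at lambda = 1."""
    return PairInteraction(
        sigma_ij=s.lambda_sigma * 0.5 * (a.sigma + b.sigma),
        epsilon_ij=s.lambda_epsilon * float(np.sqrt(a.epsilon * b.epsilon)),
        provenance="scaled-rule",
    )


def invert_lb_sigma(sigma_ij: float, sigma_i: float, lambda_sigma: float = 1.0) -> float:
    """Solve the (scaled) arithmetic-mean rule for the partner diameter."""
    return 2.0 * sigma_ij / lambda_sigma - sigma_i


def invert_lb_epsilon(epsilon_ij: float, epsilon_i: float, lambda_epsilon: float = 1.0) -> float:
    """Solve the (scaled) geometric-mean rule for the partner well depth."""
    if epsilon_i <= 0:
        raise DomainError("cannot invert geometric mean against epsilon_i <= 0")
    return (epsilon_ij / lambda_epsilon) ** 2 / epsilon_i


# Optimized Mg2+ parameter sets for TIP3P water.  sigma/epsilon are the
# ion-ion values; the scaling factors act on the combination rules for Cl-
# (Mamatkulov-Schwierz anion parameters) and for every RNA atom type.
_REGISTRY: dict[str, tuple[IonModel, tuple[ScalingFactors, ...]]] = {
    "microMg": (
        IonModel("microMg", charge=2, lj=LJParams(sigma=0.1019, epsilon=235.80)),
        (
            ScalingFactors(1.8000, 0.1000, "Cl"),
            ScalingFactors(1.1375, 0.3200, "RNA"),
        ),
    ),
    "nanoMg": (
        IonModel("nanoMg", charge=2, lj=LJParams(sigma=0.1025, epsilon=389.80)),
        (
            ScalingFactors(1.8000, 0.1000, "Cl"),
            ScalingFactors(1.1435, 0.2500, "RNA"),
        ),
    ),
}


def available_params() -> list[str]:
    """Names of the built-in parameter sets."""
    return sorted(_REGISTRY)


def builtin_params(name: str) -> tuple[IonModel, list[ScalingFactors]]:
    """Return a built-in optimized parameter set by name.

    Literature comparison sets (Allner-Villa, Mamatkulov-Schwierz, Li-Merz)
    are not hard-coded; supply them via a parameter config file instead.
    """
    try:
        ion, scalings = _REGISTRY[name]
    except KeyError:
        raise LookupError_(
            f"unknown parameter set {name!r}; available: {', '.join(available_params())}"
        ) from None
    return replace(ion), list(scalings)


def potential_curve(pair: PairInteraction, r_grid) -> np.ndarray:
    """Tabulate the pair potential on ``r_grid`` (strictly increasing, nm).

    Returns an (n, 2) array of (r, V) rows suitable for plotting or export
    as two-column text.
    """
    r = np.asarray(r_grid, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise DomainError("r_grid must be a nonempty 1-D array")
    if np.any(r <= 0):
        raise DomainError("r_grid must be strictly positive")
    if r.size > 1 and np.any(np.diff(r) <= 0):
        raise DomainError("r_grid must be strictly increasing")
    return np.column_stack([r, lj_energy(pair, r)])
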