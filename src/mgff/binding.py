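"""Ion-binding thermodynamics from 1-D free-energy profiles.

A potential of mean force F(r) along an ion-ligand distance (Mg-Ow for water
exchange, Mg-OP for phosphate binding) exhibits an inner-sphere minimum, a
barrier, and a bulk plateau.  From it we compute

* the standard-state binding affinity
      dG_b0 = -ln( int_bound 4 pi r^2 exp(-F(r)) dr / V0 )     [k_B T]
  with F anchored to zero at the bulk plateau, the bound region extending
  from the start of the grid to the barrier top, and V0 = 1.661 nm^3 the 1 M
  standard-state volume;
* the binding distance R_b (parabolic-interpolated inner minimum); and
* the barrier height relative to the inner (or outer) minimum.

Profiles are stored in k_B T units; use :meth:`FreeEnergyProfile.from_kJmol`
to convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, InputError
from .units import STANDARD_VOLUME_NM3, kT

__all__ = [
    "FreeEnergyProfile",
    "BindingSummary",
    "binding_affinity",
    "binding_distance",
    "barrier_height",
    "find_well_and_barrier",
]


@dataclass
class FreeEnergyProfile:
    """1-D free energy F (k_B T units) on a strictly increasing distance grid
    r (nm).  ``+inf`` values are permitted (hard-core regions)."""

    r: np.ndarray
    F: np.ndarray
    T: float = 300.0
    reaction_coordinate_tag: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.F.shape or self.r.size < 4:
            raise InputError("profile needs matching 1-D r and F with >= 4 points")
        if np.any(np.diff(self.r) <= 0):
            raise InputError("r grid must be strictly increasing")
        if np.any(np.isnan(self.F)) or np.any(np.isneginf(self.F)):
            raise InputError("F must be finite or +inf")

    @classmethod
    def from_kJmol(cls, r, F_kJmol, T: float = 300.0, **kw) -> "FreeEnergyProfile":
        """Build a profile from energies in kJ/mol at temperature ``T``."""
        return cls(r=np.asarray(r, float), F=np.asarray(F_kJmol, float) / kT(T), T=T, **kw)

    def shifted(self, offset: float) -> "FreeEnergyProfile":
        return FreeEnergyProfile(self.r.copy(), self.F + offset, self.T,
                                 self.reaction_coordinate_tag, dict(self.meta))


@dataclass(frozen=True)
class BindingSummary:
    dG_b0: float
    R_b: float
    barrier: float
    r_barrier: float

    def __post_init__(self) -> None:
        if not self.R_b < self.r_barrier:
            raise AnalysisError("binding distance must precede the barrier")


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> float:
    if i <= 0 or i >= x.size - 1 or not np.all(np.isfinite(y[i - 1 : i + 2])):
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    return float(x[i] + 0.5 * (y[i - 1] - y[i + 1]) / denom * (x[i] - x[i - 1]))


def find_well_and_barrier(
    profile: FreeEnergyProfile, prominence: float = 0.5
) -> tuple[int, int]:
    """Indices of the inner minimum and the first barrier top after it.

    The inner minimum is the global minimum of F; the barrier is located by
    a hysteresis walk: the running maximum after the minimum becomes the
    barrier top once F has dropped ``prominence`` k_B T below it, which
    keeps sub-k_BT noise from faking extrema.  Raises
    :class:`AnalysisError` when either feature is missing.
    """
    F = np.where(np.isfinite(profile.F), profile.F, np.inf)
    i_min = int(np.argmin(F))
    if i_min == 0 or i_min == F.size - 1 or not np.isfinite(F[i_min]):
        raise AnalysisError("profile has no interior minimum (no bound state)")
    m = i_min
    for j in range(i_min + 1, F.size):
        if F[j] > F[m]:
            m = j
        elif m > i_min and F[m] - F[j] > prominence:
            return i_min, m
    raise AnalysisError(
        f"no barrier of prominence > {prominence} k_BT after the minimum"
    )


def _bulk_anchor(profile: FreeEnergyProfile, plateau_fraction: float = 0.1) -> float:
    """Mean F over the outermost ``plateau_fraction`` of the grid; errors out
    when that tail is not flat (no detectable bulk plateau)."""
    n_tail = max(3, int(round(plateau_fraction * profile.F.size)))
    tail = profile.F[-n_tail:]
    if not np.all(np.isfinite(tail)):
        raise AnalysisError("profile tail is not finite; no bulk plateau")
    if np.ptp(tail) > 0.2:
        raise AnalysisError(
            "no bulk plateau detectable (tail spans "
            f"{np.ptp(tail):.2f} k_BT); supply a longer-range profile"
        )
    return float(np.mean(tail))


def binding_affinity(
    profile: FreeEnergyProfile,
    standard_volume: float = STANDARD_VOLUME_NM3,
    r_bound_max: float | None = None,
    jacobian: bool = True,
) -> float:
    """Standard-state binding free energy dG_b0 in k_B T.

    The bound region runs from the start of the grid to the barrier top
    (override with ``r_bound_max`` for barrier-less model profiles).  F is
    shifted so the bulk plateau (outermost 10% of the grid) averages to
    zero, making the result independent of the input offset convention.
    Set ``jacobian=False`` for profiles already carrying the 4 pi r^2
    weight.
    """
    F0 = profile.F - _bulk_anchor(profile)
    if r_bound_max is None:
        _, i_bar = find_well_and_barrier(profile)
        r_bound_max = float(profile.r[i_bar])
    mask = profile.r <= r_bound_max
    if np.count_nonzero(mask) < 2:
        raise AnalysisError("bound region covers fewer than 2 grid points")
    r = profile.r[mask]
    with np.errstate(under="ignore"):
        boltz = np.exp(-F0[mask])
    weight = 4.0 * np.pi * r**2 if jacobian else np.ones_like(r)
    integral = np.trapezoid(weight * boltz, r)
    if integral <= 0:
        raise AnalysisError("bound-region configurational integral vanished")
    return float(-np.log(integral / standard_volume))


def binding_distance(profile: FreeEnergyProfile) -> float:
    """Location R_b (nm) of the inner-sphere minimum, refined by parabolic
    interpolation; invariant under vertical shifts of F."""
    i_min, _ = find_well_and_barrier(profile)
    return _parabolic_vertex(profile.r, profile.F, i_min)


def barrier_height(profile: FreeEnergyProfile, reference: str = "inner-minimum") -> float:
    """Barrier height F(top) - F(reference minimum) in k_B T.

    ``reference`` selects the inner-sphere minimum (default) or the first
    minimum beyond the barrier (``"outer-minimum"``).
    """
    i_min, i_bar = find_well_and_barrier(profile)
    if reference == "inner-minimum":
        ref = profile.F[i_min]
    elif reference == "outer-minimum":
        F = profile.F
        i_out = None
        for i in range(i_bar + 1, F.size - 1):
            if F[i] <= F[i - 1] and F[i] < F[i + 1]:
                i_out = i
                break
        if i_out is None:
            raise AnalysisError("no outer minimum beyond the barrier")
        ref = F[i_out]
    else:
        raise InputError(f"unknown reference {reference!r}")
    return float(profile.F[i_bar] - ref)


def binding_summary(profile: FreeEnergyProfile, **kw) -> BindingSummary:
    """Convenience wrapper returning all three observables at once."""
    i_min, i_bar = find_well_and_barrier(profile)
    return BindingSummary(
        dG_b0=binding_affinity(profile, **kw),
        R_b=binding_distance(profile),
        barrier=float(profile.F[i_bar] - profile.F[i_min]),
        r_barrier=float(profile.r[i_bar]),
    )
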