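"""Kirkwood-Buff analysis of electrolyte solutions.

Kirkwood-Buff integrals

    G_ij = 4 pi  integral_0^inf  (g_ij(r) - 1) r^2 dr

link pair structure to solution thermodynamics.  For a nu_c:nu_a electrolyte
(MgCl2: nu_c = 1, nu_a = 2) the salt-salt and salt-water integrals are the
stoichiometric averages

    G_ss = (nu_c^2 G_cc + 2 nu_c nu_a G_ca + nu_a^2 G_aa) / nu^2
    G_sw = (nu_c G_cw + nu_a G_aw) / nu,          nu = nu_c + nu_a

and the activity-coefficient derivative of the salt follows as

    a_cc = 1 / (1 + rho_s (G_ss - G_sw))

which is 1 for an ideal solution and decreases as ion-ion attraction grows
relative to ion-water attraction.  Combination rules that make the cation-
anion contact too attractive therefore drive a_cc below experiment.  In
practice the running integral G(r) is averaged over a convergence window
where it has flattened.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, InputError
from .exchange import block_error
from .structure import RDF

__all__ = [
    "KBIntegral",
    "ActivityResult",
    "kb_integral",
    "activity_derivative",
    "concentration_series",
    "PAIR_KEYS",
]

#: The five ion/water pair integrals entering a_cc for a 2:1 salt:
#: cation-cation, cation-anion, anion-anion, cation-water, anion-water.
PAIR_KEYS = ("cc", "ca", "aa", "cw", "aw")

DEFAULT_WINDOW = (1.0, 1.5)


@dataclass
class KBIntegral:
    """A Kirkwood-Buff integral (nm^3) with its running integral table."""

    pair_tag: str
    G: float
    convergence_window: tuple[float, float]
    running_G: np.ndarray  # (n, 2) columns (r, G(r))

    def __post_init__(self) -> None:
        if not np.isfinite(self.G):
            raise AnalysisError(f"KB integral for {self.pair_tag} is not finite")


@dataclass(frozen=True)
class ActivityResult:
    """Activity derivative a_cc at one salt concentration (mol/L)."""

    concentration: float
    a_cc: float
    err: float = 0.0
    convention: str = "ss-sw"

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise InputError("concentration must be positive")


def running_kb_integral(rdf: RDF) -> np.ndarray:
    """Running integral G(r) = 4 pi int_0^r (g-1) s^2 ds (trapezoidal).

    The integrand (g-1) s^2 vanishes at s = 0, so the segment below the
    first grid point is closed with a zero node there; the resulting
    O(r_0^3) head error is negligible for grids starting near zero.
    """
    r = np.concatenate([[0.0], rdf.r])
    h = np.concatenate([[0.0], (rdf.g - 1.0) * rdf.r**2])
    cumulative = np.concatenate([[0.0], np.cumsum(0.5 * (h[1:] + h[:-1]) * np.diff(r))])
    return np.column_stack([r[1:], 4.0 * np.pi * cumulative[1:]])


def kb_integral(rdf: RDF, window: tuple[float, float] = DEFAULT_WINDOW) -> KBIntegral:
    """Kirkwood-Buff integral of an RDF, averaged over a convergence window.

    The running integral is computed on the full grid; ``G`` is its mean over
    ``window`` (nm), which must lie inside the RDF range.  The default 1.0 to
    1.5 nm window is standard practice for converged salt-solution RDFs.
    """
    lo, hi = window
    if not (rdf.r[0] <= lo < hi <= rdf.r[-1] + 1e-12):
        raise InputError(
            f"convergence window {window} outside RDF range ({rdf.r[0]:.3f}, {rdf.r[-1]:.3f})"
        )
    running = running_kb_integral(rdf)
    mask = (running[:, 0] >= lo) & (running[:, 0] <= hi)
    if not np.any(mask):
        raise InputError("convergence window contains no grid points")
    return KBIntegral(
        pair_tag=rdf.pair_tag,
        G=float(np.mean(running[mask, 1])),
        convergence_window=(lo, hi),
        running_G=running,
    )


def _combine(G: dict[str, float], nu_c: int, nu_a: int) -> tuple[float, float]:
    nu = nu_c + nu_a
    G_ss = (nu_c**2 * G["cc"] + 2 * nu_c * nu_a * G["ca"] + nu_a**2 * G["aa"]) / nu**2
    G_sw = (nu_c * G["cw"] + nu_a * G["aw"]) / nu
    return G_ss, G_sw


def activity_derivative(
    G: dict[str, float | KBIntegral],
    rho_salt: float,
    stoichiometry: tuple[int, int] = (1, 2),
    concentration: float | None = None,
    convention: str = "ss-sw",
) -> ActivityResult:
    """Activity derivative a_cc from the five pair KB integrals.

    ``G`` maps the keys in :data:`PAIR_KEYS` to integrals (nm^3, either bare
    floats or :class:`KBIntegral`); ``rho_salt`` is the salt number density
    in nm^-3.  ``convention`` selects the combination entering the
    denominator: ``"ss-sw"`` (default, salt-salt minus salt-water) or
    ``"ss"`` (salt-salt only); the choice is echoed in the result.
    """
    vals = {}
    for key in PAIR_KEYS:
        if key not in G:
            raise InputError(f"missing pair integral {key!r}; need all of {PAIR_KEYS}")
        v = G[key]
        vals[key] = v.G if isinstance(v, KBIntegral) else float(v)
    if rho_salt < 0:
        raise InputError("rho_salt must be nonnegative")
    nu_c, nu_a = stoichiometry
    G_ss, G_sw = _combine(vals, nu_c, nu_a)
    excess = G_ss - G_sw if convention == "ss-sw" else G_ss
    denom = 1.0 + rho_salt * excess
    if denom <= 0:
        raise AnalysisError(
            f"1 + rho_s (G_ss - G_sw) = {denom:.4g} <= 0: thermodynamically unstable input"
        )
    conc = concentration if concentration is not None else rho_salt / 0.602214076
    return ActivityResult(concentration=conc, a_cc=1.0 / denom, convention=convention)


def concentration_series(
    inputs,
    blocks: int = 3,
    window: tuple[float, float] = DEFAULT_WINDOW,
    stoichiometry: tuple[int, int] = (1, 2),
    convention: str = "ss-sw",
) -> list[ActivityResult]:
    """Per-concentration a_cc with block-averaged errors.

    ``inputs`` is an iterable of ``(concentration_molar, rdfs)`` where
    ``rdfs`` maps each of :data:`PAIR_KEYS` to either one :class:`RDF` or a
    list of per-block RDFs.  With per-block RDFs, a_cc is recomputed per
    block and the error is the block spread (three blocks by default);
    otherwise the error is 0.  Results are returned sorted by concentration,
    duplicates preserved.
    """
    results = []
    for conc, rdfs in inputs:
        rho_salt = conc * 0.602214076  # mol/L -> nm^-3
        blocked = any(isinstance(v, (list, tuple)) for v in rdfs.values())
        if blocked:
            per_block = []
            for ib in range(blocks):
                Gb = {
                    key: kb_integral(rdfs[key][ib] if isinstance(rdfs[key], (list, tuple))
                                     else rdfs[key], window).G
                    for key in PAIR_KEYS
                }
                per_block.append(
                    activity_derivative(Gb, rho_salt, stoichiometry, conc, convention).a_cc
                )
            mean, err = block_error(np.asarray(per_block), n_blocks=blocks, statistic=np.mean)
            results.append(ActivityResult(conc, mean, err, convention))
        else:
            Gs = {key: kb_integral(rdfs[key], window) for key in PAIR_KEYS}
            results.append(activity_derivative(Gs, rho_salt, stoichiometry, conc, convention))
    return sorted(results, key=lambda a: a.concentration)
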