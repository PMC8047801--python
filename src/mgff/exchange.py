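"""Water-exchange kinetics from transition counting.

Waters in the first hydration shell of Mg2+ exchange with the second shell
on the microsecond timescale.  Following each water individually through the
trajectory, a dual-cutoff indicator commits a water as *bound* to an ion
when their distance drops below ``r_bound`` and as *unbound* when it exceeds
``r_unbound``; between the cutoffs the previous committed state persists
(hysteresis), which suppresses barrier-recrossing noise.  The rate constant
follows from the total number of committed transitions N (both directions
counted) via

    p_B = n1 / (N_H2O - n1)          probability of first-shell residence
    t_B = N_Mg * p_B * t_sim         cumulative first-shell time per water
    k   = N / (2 * N_H2O * t_B)      exchange rate constant, s^-1

with n1 = 6 the first-shell coordination number.  The division by two
converts bidirectional transition counts into exchange events.  Errors come
from block averaging (two blocks by default).  A 1-D transition-state-theory
estimate from the Mg-water PMF is provided strictly as an upper bound: TST
neglects diffusive recrossing and overestimates the true rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import FreeEnergyProfile, find_well_and_barrier
from .errors import ConfigError, DomainError, InputError
from .trajectory import Trajectory, pair_distances
from .units import PS_PER_S, kT

__all__ = [
    "ShellIndicator",
    "StateSeries",
    "ExchangeStats",
    "DEFAULT_N_H2O",
    "DEFAULT_N_MG",
    "label_states",
    "count_transitions",
    "exchange_rate",
    "expected_transitions",
    "block_error",
    "tst_rate",
]

#: Ideal 1 M MgCl2 composition (water:Mg ~ 55.5:1) used when no box
#: composition is supplied; consistent with the 1 us reference trajectories.
DEFAULT_N_H2O = 2160
DEFAULT_N_MG = 39

#: Default dual cutoffs (nm): first RDF minimum / onset of the second shell
#: for Mg-Ow.  Mandatory config in serious use; rates are insensitive to the
#: exact values.
DEFAULT_R_BOUND = 0.28
DEFAULT_R_UNBOUND = 0.40


@dataclass(frozen=True)
class ShellIndicator:
    """Dual-cutoff indicator: committed bound below ``r_bound``, committed
    unbound above ``r_unbound``, hysteresis in between."""

    r_bound: float = DEFAULT_R_BOUND
    r_unbound: float = DEFAULT_R_UNBOUND

    def __post_init__(self) -> None:
        if not 0 < self.r_bound < self.r_unbound:
            raise ConfigError(
                f"need 0 < r_bound < r_unbound; got {self.r_bound}, {self.r_unbound}"
            )


@dataclass
class StateSeries:
    """Committed state per water per frame: ion index >= 0 when bound, -1
    when unbound.  Intermediate (between-cutoff) frames already carry the
    inherited committed state."""

    states: np.ndarray  # (n_frames, n_waters) int
    times: np.ndarray  # (n_frames,) ps

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        self.times = np.asarray(self.times, dtype=float)
        if self.states.ndim != 2 or self.states.shape[0] != self.times.size:
            raise InputError("states must be (n_frames, n_waters) matching times")

    @property
    def n_waters(self) -> int:
        return self.states.shape[1]

    def slice_frames(self, lo: int, hi: int) -> "StateSeries":
        return StateSeries(self.states[lo:hi], self.times[lo:hi])


@dataclass(frozen=True)
class ExchangeStats:
    """Transition counts and the derived rate constant (SI seconds)."""

    N: float
    N_H2O: int
    N_Mg: int
    t_sim: float
    p_B: float
    t_B: float
    k: float
    k_err: float = 0.0


def label_states(
    traj: Trajectory,
    ind: ShellIndicator = ShellIndicator(),
    ion_role: str = "Mg",
    water_role: str = "Ow",
    chunk: int = 200,
) -> StateSeries:
    """Assign each water a committed bound/unbound state in every frame.

    A water is committed bound to the nearest ion when that distance falls
    below ``r_bound`` and committed unbound when its distance to *every* ion
    exceeds ``r_unbound``; otherwise the previous committed state persists.
    The initial state is resolved by the nearer cutoff (midpoint rule).
    Frames are processed in chunks to bound memory.
    """
    mg = traj.group(ion_role)
    ow = traj.group(water_role)
    n_frames, n_w = ow.shape[0], ow.shape[1]
    states = np.empty((n_frames, n_w), dtype=np.int64)

    prev = None
    for lo in range(0, n_frames, chunk):
        hi = min(lo + chunk, n_frames)
        d = pair_distances(ow[lo:hi], mg[lo:hi], traj.box[lo:hi])  # (f, W, M)
        nearest = np.argmin(d, axis=2)
        dmin = np.take_along_axis(d, nearest[:, :, None], axis=2)[:, :, 0]
        for f in range(hi - lo):
            if prev is None:
                mid = 0.5 * (ind.r_bound + ind.r_unbound)
                prev = np.where(dmin[f] <= mid, nearest[f], -1)
            new = prev.copy()
            bound_mask = dmin[f] < ind.r_bound
            new[bound_mask] = nearest[f][bound_mask]
            new[dmin[f] > ind.r_unbound] = -1
            states[lo + f] = new
            prev = new
    return StateSeries(states=states, times=traj.times.copy())


def count_transitions(series: StateSeries) -> int:
    """Total number of committed-state changes over all waters, counting
    first-to-second-shell exchanges and the reverse as individual events."""
    if series.states.shape[0] < 2:
        return 0
    return int(np.sum(series.states[1:] != series.states[:-1]))


def exchange_rate(
    N: float,
    N_H2O: int = DEFAULT_N_H2O,
    N_Mg: int = DEFAULT_N_MG,
    t_sim: float = 1e-6,
    n1: int = 6,
    N_err: float = 0.0,
) -> ExchangeStats:
    """Rate constant of water exchange from a transition count.

    ``N`` is the bidirectional transition total, ``t_sim`` the simulation
    time in seconds.  ``N_err`` (optional, e.g. from block averaging)
    propagates linearly into ``k_err`` since k is proportional to N.
    """
    if t_sim <= 0:
        raise DomainError("t_sim must be positive")
    if N < 0:
        raise DomainError("N must be nonnegative")
    if N_H2O <= n1:
        raise DomainError(f"need N_H2O > n1; got N_H2O={N_H2O}, n1={n1}")
    if N_Mg <= 0:
        raise DomainError("N_Mg must be positive")
    p_B = n1 / (N_H2O - n1)
    t_B = N_Mg * p_B * t_sim
    k = N / (2.0 * N_H2O * t_B)
    k_err = N_err / (2.0 * N_H2O * t_B)
    return ExchangeStats(
        N=N, N_H2O=N_H2O, N_Mg=N_Mg, t_sim=t_sim, p_B=p_B, t_B=t_B, k=k, k_err=k_err
    )


def expected_transitions(
    k: float,
    N_H2O: int = DEFAULT_N_H2O,
    N_Mg: int = DEFAULT_N_MG,
    t_sim: float = 1e-6,
    n1: int = 6,
) -> float:
    """Invert the counting estimator: the transition count a trajectory of
    length ``t_sim`` would show at rate constant ``k`` (s^-1)."""
    if k < 0:
        raise DomainError("k must be nonnegative")
    if N_H2O <= n1:
        raise DomainError(f"need N_H2O > n1; got N_H2O={N_H2O}, n1={n1}")
    p_B = n1 / (N_H2O - n1)
    t_B = N_Mg * p_B * t_sim
    return k * 2.0 * N_H2O * t_B


def block_error(data, n_blocks: int = 2, statistic=None) -> tuple[float, float]:
    """Block-averaging mean and error.

    ``data`` is either a :class:`StateSeries` (per-block statistic defaults
    to the transition count) or a 1-D array partitioned into ``n_blocks``
    contiguous blocks (truncating any remainder; statistic defaults to the
    block sum).  Returns ``(mean, std(blocks, ddof=1)/sqrt(n_blocks))``.
    """
    if n_blocks < 2:
        raise InputError("need at least 2 blocks")
    if isinstance(data, StateSeries):
        n = data.states.shape[0]
        if n < n_blocks:
            raise InputError("series shorter than the number of blocks")
        stat = statistic or count_transitions
        size = n // n_blocks
        vals = [stat(data.slice_frames(i * size, (i + 1) * size)) for i in range(n_blocks)]
    else:
        arr = np.asarray(data, dtype=float).ravel()
        if arr.size < n_blocks:
            raise InputError("data shorter than the number of blocks")
        stat = statistic or np.sum
        size = arr.size // n_blocks
        vals = [stat(arr[i * size : (i + 1) * size]) for i in range(n_blocks)]
    vals = np.asarray(vals, dtype=float)
    return float(np.mean(vals)), float(np.std(vals, ddof=1) / np.sqrt(n_blocks))


def tst_rate(profile: FreeEnergyProfile, reduced_mass: float, T: float = 300.0) -> float:
    """1-D transition-state-theory rate from a PMF, in s^-1.

        k_TST = sqrt(k_B T / (2 pi mu)) * exp(-F(r_barrier))
                / int_well exp(-F(r)) dr

    with the well integral from the start of the grid to the barrier top and
    F in k_B T units.  ``reduced_mass`` in g/mol.  Because recrossings are
    neglected, this is an upper bound on the transition-counting rate.
    """
    if reduced_mass <= 0:
        raise DomainError("reduced mass must be positive")
    i_min, i_bar = find_well_and_barrier(profile)
    F = profile.F - profile.F[i_min]  # gauge choice; ratio is shift-invariant
    mask = profile.r <= profile.r[i_bar]
    with np.errstate(under="ignore"):
        well = np.trapezoid(np.exp(-F[mask]), profile.r[mask])
    v_thermal = np.sqrt(kT(T) / (2.0 * np.pi * reduced_mass))  # nm/ps
    k_ps = v_thermal * np.exp(-F[i_bar]) / well
    return float(k_ps * PS_PER_S)
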