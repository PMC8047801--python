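"""Synthetic fixtures with known ground truth for every analysis stage.

Each generator emits data in the exact containers the analysis modules
consume and attaches its ground truth to the object's ``meta`` dict, so the
full pipelines (labeling -> counting -> rate; RDF -> shell/KB; MSD -> D;
profile -> binding) can be validated against closed forms.

* :func:`gen_hopping_traj` - per-water two-state Markov shell hopping with a
  known exchange rate, geometrically embedded around fixed ions.  Exchange
  is modeled as memoryless: only stationary counting statistics are meant to
  be realistic, not the molecular exchange mechanism.
* :func:`gen_rdf` - parametric RDF families (ideal, gaussian-shell,
  excluded-volume) with analytic coordination numbers and Kirkwood-Buff
  integrals.
* :func:`gen_brownian` - Gaussian random walks with exact per-step variance.
* :func:`gen_profile` - analytic Gaussian-well free-energy profiles whose
  binding observables are evaluated by adaptive quadrature on the closed
  form (independent of the grid-based analysis route).
* :func:`matched_profile` - a PMF whose barrier is chosen so that an
  overdamped (Kramers) crossing rate at the physical water diffusion
  constant equals a requested hopping rate; 1-D TST on the same profile then
  bounds the counting rate from above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar
from scipy.special import ndtr

from .binding import FreeEnergyProfile
from .errors import ConfigError
from .structure import RDF
from .trajectory import Trajectory, minimum_image
from .units import PS_PER_S, STANDARD_VOLUME_NM3, kT

__all__ = [
    "HoppingSpec",
    "gen_hopping_traj",
    "gen_rdf",
    "gen_brownian",
    "gen_profile",
    "matched_profile",
    "WATER_D_NM2_PS",
    "MG_WATER_REDUCED_MASS",
]

#: Self-diffusion coefficient of water at ambient conditions, nm^2/ps.
WATER_D_NM2_PS = 2.3e-3

#: Reduced mass of the Mg2+ / H2O pair, g/mol.
MG_WATER_REDUCED_MASS = 24.305 * 18.015 / (24.305 + 18.015)


@dataclass(frozen=True)
class HoppingSpec:
    """Stated world of the shell-hopping generator.

    Defaults mirror the 1 us, 1 M MgCl2 reference conditions: ideal
    composition N_H2O:N_Mg = 2160:39 (~55.5:1), n1 = 6 shell slots per ion.
    ``k_true`` is the exchange rate constant (s^-1) that the transition-
    counting estimator recovers in expectation.  Bound waters sit at radius
    ``R1`` around their ion, bulk waters at least ``R2`` from every ion;
    both jitter by up to ``jitter`` per coordinate per frame.
    """

    k_true: float = 8.0e5
    N_Mg: int = 39
    N_H2O: int = 2160
    t_sim: float = 1.0e-6  # s
    dt: float = 1.0e-9  # s
    R1: float = 0.21  # nm
    R2: float = 0.46  # nm
    box: float = 4.2  # nm
    n1: int = 6
    jitter: float = 0.015  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 0 or self.t_sim <= 0 or self.dt <= 0:
            raise ConfigError("k_true must be >= 0 and times positive")
        if self.k_true * self.dt > 0.1:
            raise ConfigError(
                f"dt too coarse: k_true*dt = {self.k_true * self.dt:.3g} > 0.1"
            )
        if self.N_H2O <= self.n1 * self.N_Mg:
            raise ConfigError("need N_H2O > n1 * N_Mg (some bulk water)")
        if not self.R1 < self.R2:
            raise ConfigError("need R1 < R2")
        if self.R1 + math.sqrt(3) * self.jitter >= 0.28:
            raise ConfigError("R1 + jitter must stay below the default bound cutoff 0.28 nm")
        if self.R2 - math.sqrt(3) * self.jitter <= 0.40:
            raise ConfigError("R2 - jitter must stay above the default unbound cutoff 0.40 nm")

    @property
    def p_bound(self) -> float:
        """Stationary probability that a given water is bound to any ion."""
        return self.n1 * self.N_Mg / self.N_H2O

    @property
    def k_off(self) -> float:
        """Per-bound-water escape rate making the counting estimator
        unbiased for k_true (s^-1)."""
        return self.k_true * self.N_H2O / (self.N_H2O - self.n1)

    @property
    def k_on(self) -> float:
        p = self.p_bound
        return self.k_off * p / (1.0 - p)


def _ion_lattice(spec: HoppingSpec) -> np.ndarray:
    """Fixed ion positions on a cubic sublattice with safe separation."""
    per_side = math.ceil(spec.N_Mg ** (1.0 / 3.0))
    spacing = spec.box / per_side
    if spacing <= 2.0 * spec.R2:
        raise ConfigError(
            f"box too small: ion spacing {spacing:.3f} nm must exceed 2*R2 = {2 * spec.R2:.3f}"
        )
    idx = np.arange(per_side**3)[: spec.N_Mg]
    grid = np.stack(
        [idx // per_side**2, (idx // per_side) % per_side, idx % per_side], axis=1
    )
    return (grid + 0.5) * spacing


def _bulk_points(rng, n: int, ions: np.ndarray, box: float, r_excl: float) -> np.ndarray:
    """Uniform points in the box at minimum-image distance > r_excl from all
    ions (rejection sampling)."""
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        batch = rng.uniform(0.0, box, size=(max(2 * (n - filled), 16), 3))
        d = minimum_image(batch[:, None, :] - ions[None, :, :], np.full(3, box))
        ok = np.min(np.sqrt(np.sum(d * d, axis=-1)), axis=1) > r_excl
        good = batch[ok]
        take = min(good.shape[0], n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def _unit_vectors(rng, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def gen_hopping_traj(spec: HoppingSpec) -> Trajectory:
    """Generate a shell-hopping trajectory with exchange rate ``spec.k_true``.

    Each water follows an independent two-state continuous-time Markov chain
    (bound at radius R1 around a randomly chosen ion / bulk beyond R2) with
    exact exponential waiting times, discretized to frames of ``spec.dt``.
    Initially exactly ``n1`` waters occupy each ion's shell.  Deterministic
    for a fixed seed; ground truth is recorded in ``Trajectory.meta``.
    """
    rng = np.random.default_rng(spec.seed)
    ions = _ion_lattice(spec)
    n_frames = int(round(spec.t_sim / spec.dt)) + 1
    frame_t = np.arange(n_frames) * spec.dt  # seconds
    n_w = spec.N_H2O

    coords = np.empty((n_frames, n_w, 3))
    n_bound0 = spec.n1 * spec.N_Mg
    rates = {True: spec.k_off, False: spec.k_on}  # leave-rate by current boundness

    for w in range(n_w):
        bound0 = w < n_bound0
        # alternating exponential waiting times until t_sim is covered
        events: list[float] = []
        seg_bound = [bound0]
        t = 0.0
        cur = bound0
        if spec.k_true > 0:
            while t < spec.t_sim:
                t += rng.exponential(1.0 / rates[cur])
                if t >= spec.t_sim:
                    break
                events.append(t)
                cur = not cur
                seg_bound.append(cur)
        n_seg = len(seg_bound)
        # anchor per segment
        anchors = np.empty((n_seg, 3))
        for s, is_b in enumerate(seg_bound):
            if is_b:
                ion = w % spec.N_Mg if (s == 0 and bound0) else rng.integers(spec.N_Mg)
                anchors[s] = ions[ion] + spec.R1 * _unit_vectors(rng, 1)[0]
            else:
                anchors[s] = _bulk_points(rng, 1, ions, spec.box, spec.R2)[0]
        seg_idx = np.searchsorted(np.asarray(events), frame_t, side="right")
        coords[:, w, :] = anchors[seg_idx]

    coords += rng.uniform(-spec.jitter, spec.jitter, size=coords.shape)
    coords = np.mod(coords, spec.box)
    box = np.full((n_frames, 3), spec.box)
    mg = np.broadcast_to(ions, (n_frames, spec.N_Mg, 3)).copy()
    times_ps = frame_t * PS_PER_S
    return Trajectory(
        times=times_ps,
        coords={"Mg": mg, "Ow": coords},
        box=box,
        meta={
            "generator": "hopping",
            "k_true": spec.k_true,
            "k_off": spec.k_off,
            "k_on": spec.k_on,
            "p_bound": spec.p_bound,
            "spec": spec,
        },
    )


# ---------------------------------------------------------------------------
# Parametric RDFs with closed-form observables
# ---------------------------------------------------------------------------


def gen_rdf(family: str, params: dict, grid: np.ndarray) -> RDF:
    """Parametric RDF with analytic observables attached in ``meta``.

    Families (``params`` keys; ``rho`` is the partner density in nm^-3):

    - ``"ideal"``: g = 1.  Truths: G = 0; n1(r) = 4/3 pi rho r^3.
    - ``"gaussian-shell"``: a Gaussian coordination shell of area ``A``
      (molecules) centered at ``mu`` with width ``s``, plus bulk g = 1
      switched on at ``bulk_onset`` (default mu + 6 s).  Truths: n1 (shell
      integral to the onset), peak position R1, and G.
    - ``"excluded-volume"``: g = 0 below ``d``, 1 beyond.
      Truths: G = -(4/3) pi d^3.
    """
    r = np.asarray(grid, dtype=float)
    rho = float(params["rho"])
    if rho <= 0:
        raise ConfigError("rho must be positive")
    if family == "ideal":
        g = np.ones_like(r)
        meta = {"family": family, "G": 0.0, "n1_at": lambda c: 4.0 / 3.0 * np.pi * rho * c**3}
    elif family == "gaussian-shell":
        A, mu, s = float(params["A"]), float(params["mu"]), float(params["s"])
        if A < 0 or s <= 0 or mu <= 0:
            raise ConfigError("gaussian-shell needs A >= 0, mu > 0, s > 0")
        onset = float(params.get("bulk_onset", mu + 6.0 * s))
        pdf = np.exp(-0.5 * ((r - mu) / s) ** 2) / (s * math.sqrt(2.0 * math.pi))
        shell = A * pdf / (4.0 * np.pi * rho * r**2)
        # bulk g=1 switched on at the onset as a bin-averaged step so the
        # trapezoidal analyses never integrate across a raw discontinuity
        if r.size > 1:
            h = float(np.median(np.diff(r)))
            bulk = np.clip((r + 0.5 * h - onset) / h, 0.0, 1.0)
        else:
            bulk = (r >= onset).astype(float)
        g = shell + bulk
        if np.any(g < 0):
            raise ConfigError("parameters imply negative g")
        phi = lambda x: ndtr(x)  # standard normal CDF
        n1 = A * (phi((onset - mu) / s) - phi(-mu / s))  # shell mass inside [0, onset]
        G = A / rho * (1.0 - phi(-mu / s)) - 4.0 / 3.0 * np.pi * onset**3
        disc = mu * mu - 8.0 * s * s
        R1 = 0.5 * (mu + math.sqrt(disc)) if disc > 0 else mu
        meta = {"family": family, "G": G, "n1": n1, "R1": R1, "bulk_onset": onset}
    elif family == "excluded-volume":
        d = float(params["d"])
        if d <= 0:
            raise ConfigError("excluded-volume needs d > 0")
        # bin-averaged step (what a histogram estimator reports), so that
        # trapezoidal integration does not see a raw discontinuity
        if r.size > 1:
            h = float(np.median(np.diff(r)))
            g = np.clip((r + 0.5 * h - d) / h, 0.0, 1.0)
        else:
            g = np.where(r < d, 0.0, 1.0)
        meta = {
            "family": family,
            "G": -4.0 / 3.0 * np.pi * d**3,
            "n1_at": lambda c: 4.0 / 3.0 * np.pi * rho * max(c**3 - d**3, 0.0),
        }
    else:
        raise ConfigError(f"unknown RDF family {family!r}")
    return RDF(r=r, g=g, rho_bulk=rho, pair_tag=f"synthetic-{family}", meta=meta)


def gen_brownian(
    d0: float,
    n: int,
    steps: int,
    dt: float,
    box: float,
    seed: int = 0,
    role: str = "Ow",
) -> Trajectory:
    """Brownian (Gaussian random-walk) trajectory with known diffusion.

    ``d0`` is the diffusion coefficient in 1e-5 cm^2/s (the unit D0 carries
    throughout the package), ``dt`` the frame spacing in ps, ``box`` the
    cubic box length in nm.  Per-step displacement variance is exactly
    2 D dt per dimension; coordinates are wrapped (analyses unwrap).
    """
    if d0 < 0 or n <= 0 or steps < 1 or dt <= 0 or box <= 0:
        raise ConfigError("need d0 >= 0, n > 0, steps >= 1, dt > 0, box > 0")
    rng = np.random.default_rng(seed)
    D = d0 * 1.0e-3  # 1e-5 cm^2/s -> nm^2/ps
    sigma = math.sqrt(2.0 * D * dt)
    start = rng.uniform(0.0, box, size=(1, n, 3))
    disp = rng.normal(scale=sigma, size=(steps, n, 3)) if sigma > 0 else np.zeros((steps, n, 3))
    coords = np.concatenate([start, start + np.cumsum(disp, axis=0)], axis=0)
    coords = np.mod(coords, box)
    n_frames = steps + 1
    return Trajectory(
        times=np.arange(n_frames) * dt,
        coords={role: coords},
        box=np.full((n_frames, 3), box),
        meta={"generator": "brownian", "D0": d0, "D_nm2_ps": D},
    )


# ---------------------------------------------------------------------------
# Analytic free-energy profiles
# ---------------------------------------------------------------------------


def _profile_fn(well_depth, well_pos, well_width, barrier, barrier_pos, barrier_width):
    def F(r):
        r = np.asarray(r, dtype=float)
        v = -well_depth * np.exp(-0.5 * ((r - well_pos) / well_width) ** 2)
        if barrier > 0:
            v = v + barrier * np.exp(-0.5 * ((r - barrier_pos) / barrier_width) ** 2)
        return v

    return F


def gen_profile(
    well_depth: float,
    well_pos: float,
    barrier: float,
    barrier_pos: float,
    grid: np.ndarray,
    well_width: float = 0.015,
    barrier_width: float = 0.012,
    T: float = 300.0,
    standard_volume: float = STANDARD_VOLUME_NM3,
) -> FreeEnergyProfile:
    """Gaussian-well free-energy profile with closed-form binding truths.

    F(r) = -depth * exp(-(r-r0)^2/2w^2) + barrier * exp(-(r-rb)^2/2wb^2),
    in k_B T units.  The attached truths (``meta``: ``dG_b0``, ``R_b``,
    ``barrier``, ``r_barrier``) are computed on the analytic form with
    adaptive quadrature and bounded scalar optimization - an independent
    route from the grid-based analysis.
    """
    if barrier > 0 and barrier_pos <= well_pos:
        raise ConfigError("barrier_pos must exceed well_pos")
    grid = np.asarray(grid, dtype=float)
    F = _profile_fn(well_depth, well_pos, well_width, barrier, barrier_pos, barrier_width)

    meta: dict = {"generator": "gaussian-well", "well_depth": well_depth, "well_pos": well_pos}
    if well_depth > 0:
        res = minimize_scalar(
            F, bounds=(max(grid[0], well_pos - 3 * well_width), well_pos + 3 * well_width),
            method="bounded",
        )
        r_b_true = float(res.x)
    else:
        r_b_true = well_pos
    if barrier > 0:
        res = minimize_scalar(
            lambda r: -F(r),
            bounds=(well_pos, barrier_pos + 3 * barrier_width),
            method="bounded",
        )
        r_dagger = float(res.x)
        meta["barrier"] = float(F(r_dagger) - F(r_b_true))
        meta["r_barrier"] = r_dagger
    else:
        r_dagger = grid[-1]
    integral, _ = quad(
        lambda r: 4.0 * np.pi * r**2 * math.exp(-float(F(r))), grid[0], r_dagger, limit=200
    )
    meta["dG_b0"] = -math.log(integral / standard_volume)
    meta["R_b"] = r_b_true
    return FreeEnergyProfile(r=grid, F=F(grid), T=T, reaction_coordinate_tag="MgOw", meta=meta)


def matched_profile(
    k_true: float,
    R1: float = 0.21,
    R2: float = 0.46,
    D: float = WATER_D_NM2_PS,
    T: float = 300.0,
    well_width: float = 0.02,
    barrier_width: float = 0.02,
    bump: float = 1.0,
    n_points: int = 2000,
) -> FreeEnergyProfile:
    """PMF whose overdamped escape rate equals ``k_true``.

    The well depth B at R1 is found by inverting the high-barrier Kramers
    rate for diffusive dynamics at diffusion constant ``D`` (nm^2/ps),

        k = D / (2 pi) * sqrt(F''_well |F''_barrier|) * exp(-dF),

    with a small bump of height ``bump`` k_B T at the barrier position
    midway between R1 and R2 (dF = B + bump).  Because transition-state
    theory replaces diffusive barrier crossing by free thermal flight, TST
    evaluated on this profile exceeds the generating rate whenever
    v_thermal * barrier_width > D - which holds by orders of magnitude for
    water - making (hopping trajectory, matched profile) pairs a valid
    TST-upper-bound benchmark.
    """
    if k_true <= 0:
        raise ConfigError("k_true must be positive")
    k_ps = k_true / PS_PER_S
    barrier_pos = 0.5 * (R1 + R2)

    def rate_minus_target(B):
        curv_w = B / well_width**2
        curv_b = bump / barrier_width**2
        return D / (2 * np.pi) * np.sqrt(curv_w * curv_b) * np.exp(-(B + bump)) - k_ps

    B = brentq(rate_minus_target, 1e-3, 80.0)
    grid = np.linspace(max(0.05, R1 - 5 * well_width), R2 + 6 * barrier_width, n_points)
    prof = gen_profile(
        well_depth=B,
        well_pos=R1,
        barrier=bump,
        barrier_pos=barrier_pos,
        grid=grid,
        well_width=well_width,
        barrier_width=barrier_width,
        T=T,
    )
    prof.meta.update({"generator": "kramers-matched", "k_true": k_true, "B": B, "D": D})
    return prof
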