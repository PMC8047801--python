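"""Solution-structure observables: RDFs, first hydration shell, diffusion.

The first hydration shell of Mg2+ is characterized by the position R1 of the
first peak of the Mg-O radial distribution function, the position of the
first minimum, and the coordination number

    n1 = 4 pi rho_bulk  integral_0^{r_min1}  g(r) r^2 dr

(six octahedrally arranged waters for Mg2+).  The self-diffusion coefficient
D0 comes from the Einstein relation, D = slope(MSD)/6, fitted over a time
window with time-origin averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, GeometryError, InputError
from .trajectory import Trajectory, minimum_image, pair_distances
from .units import NM2_PER_PS_TO_1E5_CM2_S

__all__ = ["RDF", "ShellSummary", "compute_rdf", "first_shell", "msd_diffusion"]


@dataclass
class RDF:
    """Radial distribution function on uniform bins.

    ``r`` holds bin centers (nm), ``g`` the dimensionless values,
    ``rho_bulk`` the number density of the partner species (nm^-3).
    ``counts`` optionally carries the raw pair histogram for bookkeeping.
    """

    r: np.ndarray
    g: np.ndarray
    rho_bulk: float
    pair_tag: str = ""
    counts: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.g.shape:
            raise InputError("r and g must be 1-D arrays of equal length")
        if np.any(self.r <= 0) or (self.r.size > 1 and np.any(np.diff(self.r) <= 0)):
            raise InputError("r must be positive and strictly increasing")
        if np.any(self.g < 0):
            raise InputError("g must be nonnegative")
        if self.rho_bulk <= 0:
            raise InputError("rho_bulk must be positive")


@dataclass(frozen=True)
class ShellSummary:
    """First-shell geometry: peak position R1, first-minimum position, and
    coordination number n1."""

    R1: float
    r_min1: float
    n1: float

    def __post_init__(self) -> None:
        if not (0 < self.R1 < self.r_min1):
            raise AnalysisError(f"need 0 < R1 < r_min1; got R1={self.R1}, r_min1={self.r_min1}")
        if self.n1 < 0:
            raise AnalysisError("n1 must be nonnegative")


def compute_rdf(
    traj: Trajectory,
    pair: tuple[str, str],
    bin_width: float = 0.002,
    r_max: float | None = None,
) -> RDF:
    """Estimate the radial distribution function between two roles.

    Minimum-image pair distances are histogrammed over all frames and
    normalized by the ideal-gas shell count.  ``r_max`` defaults to (and must
    not exceed) half the smallest box length.  The default 0.002 nm bins
    resolve the narrow Mg-O first peak to the precision R1 is quoted at.
    """
    role_a, role_b = pair
    a = traj.group(role_a)
    b = traj.group(role_b)
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise InputError(f"empty atom group in pair {pair}")
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    half_box = float(np.min(traj.box) / 2.0)
    if r_max is None:
        r_max = half_box
    if r_max > half_box + 1e-12:
        raise GeometryError(f"r_max={r_max} exceeds half the smallest box length {half_box}")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    d = pair_distances(a, b, traj.box)
    same = role_a == role_b
    if same:
        iu = np.triu_indices(a.shape[1], k=1)
        d = d[:, iu[0], iu[1]]
    hist, _ = np.histogram(d.ravel(), bins=edges)

    volume = float(np.mean(np.prod(traj.box, axis=1)))
    n_a, n_b = a.shape[1], b.shape[1]
    n_pairs = n_a * (n_a - 1) / 2.0 if same else float(n_a * n_b)
    rho_pairs = n_pairs / volume  # pair density per central atom handled below
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = traj.n_frames * rho_pairs * shell_vol
    g = np.where(ideal > 0, hist / ideal, 0.0)
    rho_bulk = (n_b - 1 if same else n_b) / volume
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDF(
        r=centers,
        g=g,
        rho_bulk=rho_bulk,
        pair_tag=f"{role_a}-{role_b}",
        counts=hist,
        meta={"n_frames": traj.n_frames, "n_pairs": n_pairs, "volume_nm3": volume},
    )


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex abscissa of the parabola through three equally indexed points
    around ``i``; falls back to x[i] at the array edge or for a degenerate
    parabola."""
    if i <= 0 or i >= x.size - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(x[i] + delta * (x[i] - x[i - 1]))


def _moving_average3(y: np.ndarray) -> np.ndarray:
    pad = np.concatenate([y[:1], y, y[-1:]])
    return (pad[:-2] + pad[1:-1] + pad[2:]) / 3.0


def shell_integral(rdf: RDF, r_cut: float) -> float:
    """Coordination number 4 pi rho int_0^{r_cut} g r^2 dr (trapezoidal, on
    the unsmoothed g, with the integrand taken as 0 at r=0)."""
    mask = rdf.r <= r_cut * (1.0 + 1e-12) + 1e-12
    r = np.concatenate([[0.0], rdf.r[mask]])
    integrand = np.concatenate([[0.0], rdf.g[mask] * rdf.r[mask] ** 2])
    return float(4.0 * np.pi * rdf.rho_bulk * np.trapezoid(integrand, r))


def first_shell(rdf: RDF, r_min1: float | None = None) -> ShellSummary:
    """Locate the first peak and minimum of an RDF and integrate the shell.

    Extremum detection runs on a 3-bin moving average of g to avoid
    noise-induced minima; the peak position R1 is refined by parabolic
    interpolation through three bins, and the coordination number integrates
    the *unsmoothed* g.  ``r_min1`` may be forced (e.g. for a flat RDF).
    """
    g_s = _moving_average3(rdf.g)
    if r_min1 is None:
        i_peak = None
        for i in range(1, g_s.size - 1):
            if g_s[i] >= g_s[i - 1] and g_s[i] > g_s[i + 1]:
                i_peak = i
                break
        if i_peak is None:
            raise AnalysisError("RDF has no interior maximum (monotone or flat g)")
        i_min = None
        for i in range(i_peak + 1, g_s.size - 1):
            if g_s[i] <= g_s[i - 1] and g_s[i] < g_s[i + 1]:
                i_min = i
                break
        if i_min is None:
            raise AnalysisError("no first minimum found after the first peak")
        r_min1 = float(rdf.r[i_min])
    else:
        after = rdf.r < r_min1
        if not np.any(after):
            raise AnalysisError("forced r_min1 lies below the grid")
        seg = g_s[after]
        i_peak = int(np.argmax(seg))
    R1 = _parabolic_vertex(rdf.r, g_s, i_peak)
    return ShellSummary(R1=R1, r_min1=r_min1, n1=shell_integral(rdf, r_min1))


def _unwrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping by accumulating minimum-image frame-to-frame
    displacements (valid when no particle moves more than half a box length
    per frame)."""
    steps = minimum_image(np.diff(coords, axis=0), box[1:, None, :])
    out = np.empty_like(coords)
    out[0] = coords[0]
    out[1:] = coords[0] + np.cumsum(steps, axis=0)
    return out


def msd_diffusion(
    traj: Trajectory,
    role: str,
    fit_window: tuple[float, float],
    n_blocks: int = 5,
    max_lags: int = 100,
) -> tuple[float, float]:
    """Self-diffusion coefficient from the Einstein relation.

    The mean-squared displacement is averaged over all time origins and
    particles, a least-squares line is fitted over lag times inside
    ``fit_window`` (ps), and D = slope/6 is converted to 1e-5 cm^2/s.  The
    uncertainty is the block-averaging error over ``n_blocks`` contiguous
    trajectory blocks.

    Returns ``(D0, D0_err)``.
    """
    xyz = _unwrap(traj.group(role), traj.box)
    dt = float(np.mean(np.diff(traj.times)))
    lo, hi = fit_window
    if lo < 0 or hi > traj.times[-1] - traj.times[0] or hi <= lo:
        raise InputError("fit window must lie inside the trajectory span")
    lag_min = max(1, int(round(lo / dt)))
    lag_max = int(round(hi / dt))
    if lag_max - lag_min + 1 < 3:
        raise InputError("fit window must cover at least 3 frames")
    lags = np.unique(np.linspace(lag_min, lag_max, min(max_lags, lag_max - lag_min + 1)).astype(int))

    def _fit(block: np.ndarray) -> float:
        msd = np.empty(lags.size)
        for k, lag in enumerate(lags):
            disp = block[lag:] - block[:-lag]
            msd[k] = np.mean(np.sum(disp * disp, axis=-1))
        slope = np.polyfit(lags * dt, msd, 1)[0]
        return slope / 6.0 * NM2_PER_PS_TO_1E5_CM2_S

    d_full = _fit(xyz)
    # block errors: refit on contiguous sub-trajectories long enough to hold
    # the largest lag; otherwise report 0 spread
    n_frames = xyz.shape[0]
    block_len = n_frames // n_blocks
    if block_len > lags[-1] + 2:
        d_blocks = [_fit(xyz[i * block_len : (i + 1) * block_len]) for i in range(n_blocks)]
        err = float(np.std(d_blocks, ddof=0) / np.sqrt(n_blocks))
    else:
        err = 0.0
    return float(d_full), err
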