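"""Three-step force-field parameter selection on observable tables.

The optimization is engine-agnostic: candidates are rows of precomputed
observables (from MD runs or any other source), and the selection logic is
pure table arithmetic.

Step 1 (hydration): keep every (sigma_io, epsilon_io) grid point whose
solvation free energy and first-shell distance fall within tolerance of
experiment and whose coordination number matches exactly (n1 = 6).

Step 2 (kinetics): among the survivors, pick the candidate whose water-
exchange rate matches the experimental rate (on a log scale), or the fastest
one - the latter yields nanosecond-scale exchange dynamics that make
ion-binding events directly observable.

Step 3 (scaling): grid search over combination-rule scaling factors; the Cl
stage matches the MgCl2 activity derivative a_cc, the RNA stage selects rows
within the binding-distance tolerance and then minimizes the binding-
affinity error.  The experimental dG_b0 derives from the DMP stability
constant via dG_b0 = -ln(10) * logK.

Ties always break toward the smallest first parameter, then the smallest
second parameter, so identical tables select identical rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, MgffError

__all__ = [
    "ObservableSet",
    "CandidateRow",
    "TargetSpec",
    "DEFAULT_TARGETS",
    "SEARCH_RANGES",
    "log_stability_to_kT",
    "filter_hydration",
    "select_kinetics",
    "select_scaling",
    "candidates_from_frame",
    "SelectionError",
]


class SelectionError(MgffError, RuntimeError):
    """No candidate satisfied the selection stage."""


#: Declared grid-search ranges; candidates outside them trigger a warning.
SEARCH_RANGES = {
    "sigma_io": (0.16, 0.24),  # nm
    "epsilon_io": (1.8, 28.0),  # kJ/mol
    "lambda_sigma_Cl": (1.0, 2.6),
    "lambda_epsilon_Cl": (0.01, 1.0),
    "lambda_sigma_RNA": (0.97, 1.23),
    "lambda_epsilon_RNA": (0.08, 1.04),
}


def log_stability_to_kT(log_K: float) -> float:
    """Convert a log10 stability constant to a binding free energy in k_B T:
    dG_b0 = -ln(10) * logK (logK = 0.45 -> -1.036 k_B T)."""
    return -math.log(10.0) * log_K


@dataclass
class ObservableSet:
    """Observable vector for one candidate; any subset may be present
    (missing entries are None)."""

    dG_solv: float | None = None  # kJ/mol
    R1: float | None = None  # nm
    n1: int | None = None
    k_exchange: float | None = None  # s^-1
    D0: float | None = None  # 1e-5 cm^2/s
    a_cc: float | None = None
    dG_b0: float | None = None  # k_B T
    R_b: float | None = None  # nm

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise InputError(f"candidate lacks required observables: {missing}")


@dataclass
class CandidateRow:
    """One grid point: parameters (either (sigma_io, epsilon_io) in
    nm/kJ/mol or (lambda_sigma, lambda_epsilon)) plus its observables."""

    params: tuple[float, float]
    observables: ObservableSet
    label: str = ""

    def sort_key(self) -> tuple[float, float]:
        return (self.params[0], self.params[1])


@dataclass
class TargetSpec:
    """Experimental target values with absolute tolerances.

    Each entry maps an observable name to ``(value, tolerance)``; n1 is an
    exact integer match and carries no tolerance.
    """

    targets: dict[str, tuple[float, float]] = field(default_factory=dict)

    def value(self, name: str) -> float:
        return self.targets[name][0]

    def tol(self, name: str) -> float:
        return self.targets[name][1]

    def __post_init__(self) -> None:
        for name, (_, tol) in self.targets.items():
            if name != "n1" and tol <= 0:
                raise InputError(f"tolerance for {name!r} must be positive")


#: Experimental targets with default tolerances (R1 tolerance is the
#: experimental uncertainty; dG_solv and a_cc tolerances are package
#: defaults).
DEFAULT_TARGETS = TargetSpec(
    {
        "dG_solv": (-2532.0, 5.0),
        "R1": (0.209, 0.004),
        "n1": (6, 0),
        "k_exchange": (6.7e5, np.inf),
        "a_cc": (0.93, 0.02),
        "dG_b0": (log_stability_to_kT(0.45), 0.5),
        "R_b": (0.207, 0.001),
    }
)


def filter_hydration(
    cands: list[CandidateRow], targets: TargetSpec = DEFAULT_TARGETS
) -> list[CandidateRow]:
    """Step 1: retain candidates matching dG_solv and R1 within tolerance and
    n1 exactly.  An empty result is returned with a warning, not an error."""
    kept = []
    for c in cands:
        c.observables.require("dG_solv", "R1", "n1")
        ok = (
            abs(c.observables.dG_solv - targets.value("dG_solv")) <= targets.tol("dG_solv")
            and abs(c.observables.R1 - targets.value("R1")) <= targets.tol("R1")
            and int(c.observables.n1) == int(targets.value("n1"))
        )
        if ok:
            kept.append(c)
    if not kept:
        warnings.warn("hydration filter retained no candidates", stacklevel=2)
    return sorted(kept, key=CandidateRow.sort_key)


def select_kinetics(
    cands: list[CandidateRow], k_exp: float = 6.7e5, mode: str = "match-experiment"
) -> CandidateRow:
    """Step 2: pick the candidate with the exchange rate closest to
    experiment on a log10 scale (``match-experiment``) or the fastest one
    (``fastest``)."""
    if not cands:
        raise SelectionError("no candidates supplied to the kinetics stage")
    for c in cands:
        c.observables.require("k_exchange")
    ordered = sorted(cands, key=CandidateRow.sort_key)
    if mode == "match-experiment":
        if k_exp <= 0:
            raise InputError("k_exp must be positive")
        return min(ordered, key=lambda c: abs(math.log10(c.observables.k_exchange / k_exp)))
    if mode == "fastest":
        return max(ordered, key=lambda c: (c.observables.k_exchange, [-p for p in c.params]))
    raise InputError(f"unknown kinetics mode {mode!r}")


def _check_ranges(cands: list[CandidateRow], stage: str) -> None:
    lo_s, hi_s = SEARCH_RANGES[f"lambda_sigma_{stage}"]
    lo_e, hi_e = SEARCH_RANGES[f"lambda_epsilon_{stage}"]
    for c in cands:
        ls, le = c.params
        if not (lo_s <= ls <= hi_s and lo_e <= le <= hi_e):
            warnings.warn(
                f"candidate lambda=({ls}, {le}) outside the declared {stage} "
                f"search range sigma:[{lo_s}, {hi_s}] eps:[{lo_e}, {hi_e}]",
                stacklevel=3,
            )


def select_scaling(
    cands: list[CandidateRow],
    targets: TargetSpec = DEFAULT_TARGETS,
    stage: str = "Cl",
) -> CandidateRow:
    """Step 3: pick combination-rule scaling factors.

    ``stage="Cl"``: minimize |a_cc - target|.  ``stage="RNA"``: restrict to
    rows whose R_b lies within tolerance of the experimental inner-sphere
    distance, then minimize |dG_b0 - target|.
    """
    if not cands:
        raise SelectionError(f"no candidates supplied to the {stage} scaling stage")
    if stage not in ("Cl", "RNA"):
        raise InputError(f"unknown scaling stage {stage!r}")
    _check_ranges(cands, stage)
    ordered = sorted(cands, key=CandidateRow.sort_key)
    if stage == "Cl":
        for c in ordered:
            c.observables.require("a_cc")
        return min(ordered, key=lambda c: abs(c.observables.a_cc - targets.value("a_cc")))
    for c in ordered:
        c.observables.require("dG_b0", "R_b")
    feasible = [
        c for c in ordered
        if abs(c.observables.R_b - targets.value("R_b")) <= targets.tol("R_b")
    ]
    if not feasible:
        raise SelectionError("no candidate satisfies the R_b tolerance in the RNA stage")
    return min(feasible, key=lambda c: abs(c.observables.dG_b0 - targets.value("dG_b0")))


_PARAM_COLUMNS = (("sigma_io", "epsilon_io"), ("lambda_sigma", "lambda_epsilon"))
_OBS_COLUMNS = ("dG_solv", "R1", "n1", "k_exchange", "D0", "a_cc", "dG_b0", "R_b")


def candidates_from_frame(df: pd.DataFrame) -> list[CandidateRow]:
    """Build candidate rows from a DataFrame (e.g. ``pd.read_csv``) whose
    header names the parameter pair and any subset of the observables."""
    for pcols in _PARAM_COLUMNS:
        if all(c in df.columns for c in pcols):
            break
    else:
        raise InputError(
            f"table must name a parameter pair: one of {_PARAM_COLUMNS}; got {list(df.columns)}"
        )
    rows = []
    for _, rec in df.iterrows():
        obs = {}
        for name in _OBS_COLUMNS:
            if name in df.columns and pd.notna(rec[name]):
                obs[name] = int(rec[name]) if name == "n1" else float(rec[name])
        rows.append(
            CandidateRow(
                params=(float(rec[pcols[0]]), float(rec[pcols[1]])),
                observables=ObservableSet(**obs),
                label=str(rec.get("label", "")),
            )
        )
    return rows
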