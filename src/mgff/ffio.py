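"""File formats: two-column XVG-tolerant tables, TOML parameter sets, and
GROMACS topology-include (.itp) snippets with explicit pair overrides.

Scaled combination rules cannot be expressed through GROMACS' global
combination rule, so every scaled pair is materialized as an explicit
``[ nonbond_params ]`` override computed via :func:`mgff.ffmodel.combine_scaled`;
ion-water pairs are deliberately left to the engine's standard rules, which
keeps single-ion properties untouched.  Emission is canonical: parsing
emitted text and re-emitting reproduces it byte for byte.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

import numpy as np

from .binding import FreeEnergyProfile
from .errors import ConfigError, InputError, ParseError
from .ffmodel import IonModel, LJParams, PairInteraction, ScalingFactors, combine_scaled
from .structure import RDF

__all__ = [
    "TopologySnippet",
    "emit_itp",
    "format_itp",
    "parse_itp",
    "read_table",
    "write_table",
    "read_rdf",
    "write_rdf",
    "read_profile",
    "write_profile",
    "read_params",
    "write_params",
]

ION_MASSES = {"MG": (12, 24.305), "CL": (17, 35.453), "NA": (11, 22.990), "K": (19, 39.098)}


@dataclass
class TopologySnippet:
    """Parsed/emittable topology include: atomtype records
    (name, at_num, mass, charge, sigma, epsilon) and pair-override records
    (type_i, type_j, sigma_ij, epsilon_ij)."""

    atomtypes: list[tuple[str, int, float, float, float, float]] = field(default_factory=list)
    pairs: list[tuple[str, str, float, float]] = field(default_factory=list)
    dialect: str = "gromacs"

    def __post_init__(self) -> None:
        seen = set()
        for ti, tj, *_ in self.pairs:
            key = tuple(sorted((ti, tj)))
            if key in seen:
                raise ConfigError(f"duplicate pair override {ti}-{tj}")
            seen.add(key)


def emit_itp(
    ion: IonModel,
    scalings: list[ScalingFactors],
    partner_types: list[tuple[str, LJParams, str]],
    type_name: str | None = None,
) -> tuple[TopologySnippet, str]:
    """Materialize an ion plus its scaled pair interactions as .itp text.

    ``partner_types`` holds (GROMACS type name, LJ parameters, class) where
    class is one of ``Cl``, ``RNA``, ``water``, ``other``.  Each scaling's
    ``species_tag`` must match at least one partner class; matching partners
    get one explicit override each, computed with the scaled rules.  Water
    and unscaled classes get none (engine-level standard rules apply).

    Returns the snippet and its canonical text.
    """
    name = (type_name or ion.name).upper()[:6]
    at_num, mass = ION_MASSES.get(name, (0, 0.0))
    snippet = TopologySnippet(
        atomtypes=[(name, at_num, mass, float(ion.charge), ion.lj.sigma, ion.lj.epsilon)]
    )
    classes = {cls for _, _, cls in partner_types}
    for s in scalings:
        if s.species_tag not in classes:
            raise ConfigError(
                f"scaling tag {s.species_tag!r} matches no partner class; "
                f"available classes: {sorted(classes)}"
            )
        if s.lambda_sigma == 1.0 and s.lambda_epsilon == 1.0:
            continue  # identical to the engine's standard rules: no override
        for tname, lj, cls in partner_types:
            if cls == s.species_tag:
                pair = combine_scaled(ion.lj, lj, s)
                snippet.pairs.append((name, tname, pair.sigma_ij, pair.epsilon_ij))
    return snippet, format_itp(snippet)


def format_itp(snippet: TopologySnippet) -> str:
    """Canonical GROMACS .itp text for a snippet (combination-rule 2
    semantics: sigma/epsilon columns, >= 6 significant digits)."""
    lines = ["[ atomtypes ]", "; name  at.num      mass    charge  ptype         sigma       epsilon"]
    for name, at_num, mass, charge, sigma, eps in snippet.atomtypes:
        lines.append(
            f"{name:>6}  {at_num:6d}  {mass:8.4f}  {charge:8.4f}      A  {sigma:.6e}  {eps:.6e}"
        )
    lines += ["", "[ nonbond_params ]", ";    i       j  func         sigma       epsilon"]
    for ti, tj, sigma, eps in snippet.pairs:
        lines.append(f"{ti:>6}  {tj:>6}     1  {sigma:.6e}  {eps:.6e}")
    return "\n".join(lines) + "\n"


def parse_itp(text: str) -> TopologySnippet:
    """Parse a topology include produced by :func:`format_itp` (tolerant of
    comments and blank lines); inverse of emission on its own output."""
    snippet = TopologySnippet()
    section = None
    for lineno, raw in enumerate(text.split("\n"), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            if section not in ("atomtypes", "nonbond_params"):
                raise ParseError(f"line {lineno}: unknown section [ {section} ]")
            continue
        parts = line.split()
        try:
            if section == "atomtypes":
                if len(parts) != 7 or parts[4] != "A":
                    raise ValueError("expected: name at.num mass charge A sigma epsilon")
                snippet.atomtypes.append(
                    (parts[0], int(parts[1]), float(parts[2]), float(parts[3]),
                     float(parts[5]), float(parts[6]))
                )
            elif section == "nonbond_params":
                if len(parts) != 5 or parts[2] != "1":
                    raise ValueError("expected: i j 1 sigma epsilon")
                snippet.pairs.append((parts[0], parts[1], float(parts[3]), float(parts[4])))
            else:
                raise ValueError("record outside any section")
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}: {raw!r}") from None
    return snippet


# ---------------------------------------------------------------------------
# Two-column whitespace tables (XVG dialect tolerated on read)
# ---------------------------------------------------------------------------


def read_table(path) -> tuple[np.ndarray, dict]:
    """Read a whitespace-delimited numeric table, skipping ``#`` comments and
    XVG ``@``/``&`` metadata lines.  ``# key = value`` comments are returned
    as metadata (floats where possible)."""
    rows, meta = [], {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("@", "&")):
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError:
                        meta[key.strip()] = val.strip()
                continue
            try:
                rows.append([float(x) for x in line.split()])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    if not rows:
        raise InputError(f"no numeric rows in {path}")
    return np.asarray(rows, dtype=float), meta


def write_table(path, data: np.ndarray, meta: dict | None = None, comment: str = "") -> None:
    """Write a numeric table as whitespace text with ``#`` header lines."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key} = {val}\n")
        for row in data:
            fh.write("  ".join(f"{x: .8e}" for x in row) + "\n")


def write_rdf(path, rdf: RDF) -> None:
    write_table(
        path,
        np.column_stack([rdf.r, rdf.g]),
        meta={"pair": rdf.pair_tag, "rho_bulk": rdf.rho_bulk},
        comment="radial distribution function: r [nm], g(r)",
    )


def read_rdf(path, rho_bulk: float | None = None, pair_tag: str = "") -> RDF:
    data, meta = read_table(path)
    rho = rho_bulk if rho_bulk is not None else meta.get("rho_bulk")
    if rho is None:
        raise InputError(f"{path}: rho_bulk neither in header nor supplied")
    return RDF(r=data[:, 0], g=data[:, 1], rho_bulk=float(rho),
               pair_tag=str(meta.get("pair", pair_tag)))


def write_profile(path, profile: FreeEnergyProfile) -> None:
    write_table(
        path,
        np.column_stack([profile.r, profile.F]),
        meta={"units": "kBT", "T": profile.T, "tag": profile.reaction_coordinate_tag},
        comment="free-energy profile: r [nm], F [kBT]",
    )


def read_profile(path, units: str | None = None, T: float | None = None) -> FreeEnergyProfile:
    """Read a two-column profile.  ``units`` = ``kBT`` (default) or
    ``kJ/mol`` (requires ``T``); header metadata wins when present."""
    data, meta = read_table(path)
    units = units or str(meta.get("units", "kBT"))
    T = float(T if T is not None else meta.get("T", 300.0))
    tag = str(meta.get("tag", ""))
    if units.lower() in ("kbt", "kt"):
        return FreeEnergyProfile(r=data[:, 0], F=data[:, 1], T=T, reaction_coordinate_tag=tag)
    if units.lower() in ("kj/mol", "kjmol", "kj"):
        return FreeEnergyProfile.from_kJmol(data[:, 0], data[:, 1], T=T,
                                            reaction_coordinate_tag=tag)
    raise InputError(f"unknown profile units {units!r}")


# ---------------------------------------------------------------------------
# Parameter-set config (TOML)
# ---------------------------------------------------------------------------


def write_params(path, ion: IonModel, scalings: list[ScalingFactors]) -> None:
    """Serialize a parameter set as flat TOML: one [species] block plus one
    [[scaling]] block per partner class."""
    lines = [
        "[species]",
        f'name = "{ion.name}"',
        f"charge = {ion.charge}",
        f"sigma_nm = {ion.lj.sigma!r}",
        f"epsilon_kJmol = {ion.lj.epsilon!r}",
    ]
    for s in scalings:
        lines += [
            "",
            "[[scaling]]",
            f'species_tag = "{s.species_tag}"',
            f"lambda_sigma = {s.lambda_sigma!r}",
            f"lambda_epsilon = {s.lambda_epsilon!r}",
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_params(path) -> tuple[IonModel, list[ScalingFactors]]:
    """Read a parameter set written by :func:`write_params` (or hand-written
    in the same schema, e.g. for literature comparison sets)."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    try:
        sp = doc["species"]
        ion = IonModel(
            name=sp["name"],
            charge=sp["charge"],
            lj=LJParams(sigma=sp["sigma_nm"], epsilon=sp["epsilon_kJmol"]),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing species key {exc}") from None
    scalings = [
        ScalingFactors(
            lambda_sigma=s["lambda_sigma"],
            lambda_epsilon=s["lambda_epsilon"],
            species_tag=s["species_tag"],
        )
        for s in doc.get("scaling", [])
    ]
    return ion, scalings
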