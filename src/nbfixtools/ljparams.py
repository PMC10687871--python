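"""Pair-specific Lennard-Jones parameters for the 0BPh NBfix correction.

The correction breaks the Lorentz-Berthelot combination rules for the
intranucleotide base-phosphate contact: the minimum-energy distance
R_ij of the H8···O5' (atom types H5-OR/OS) and H6···O5' (H4-OR/OS)
12-6 terms is shifted by a signed offset (default -0.25 Å) while the
well depth is left at its combination-rule value.

The 12-6 potential uses the A/R form

    U(r) = eps * [ (r_min / r)^12 - 2 (r_min / r)^6 ]

whose minimum is exactly -eps at r = r_min.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources
import numpy as np
import yaml

__all__ = [
    "AtomType",
    "PairLJ",
    "NBfixTable",
    "ScanGrid",
    "load_atom_types",
    "combine_lorentz_berthelot",
    "apply_nbfix",
    "lj_energy",
    "build_nbfix_table",
    "make_scan_grid",
    "write_patch",
    "read_patch",
]

#: role labels required per force-field flavor, mapped to the bridging-O type
FLAVORS = {
    "RNA-OL3CP": ("OR", "bridging-O-RNA"),
    "DNA-OL15": ("OS", "bridging-O-DNA"),
}

_DONOR_ROLES = ("purine-H8", "pyrimidine-H6")


class InvalidAtomTypeError(ValueError):
    pass


class InvalidOffsetError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


class UnsupportedFormatError(ValueError):
    pass


@dataclass(frozen=True)
class AtomType:
    """A van der Waals atom type (rmin_half in Å, eps in kcal/mol)."""

    name: str
    rmin_half: float
    eps: float
    role: str

    def __post_init__(self) -> None:
        if self.rmin_half <= 0:
            raise InvalidAtomTypeError(
                f"atom type {self.name!r}: rmin_half must be > 0, got {self.rmin_half}"
            )
        if self.eps < 0:
            raise InvalidAtomTypeError(
                f"atom type {self.name!r}: eps must be >= 0, got {self.eps}"
            )


@dataclass(frozen=True)
class PairLJ:
    """One pairwise 12-6 interaction: minimum-energy distance and well depth."""

    type_i: str
    type_j: str
    r_min: float
    eps: float
    origin: str = "combination-rule"  # or "nbfix"

    def __post_init__(self) -> None:
        if self.r_min <= 0:
            raise InvalidOffsetError(
                f"pair {self.type_i}-{self.type_j}: r_min must be > 0, got {self.r_min}"
            )
        if self.eps < 0:
            raise InvalidAtomTypeError(
                f"pair {self.type_i}-{self.type_j}: eps must be >= 0, got {self.eps}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.type_i, self.type_j)


@dataclass(frozen=True)
class NBfixTable:
    """The complete set of modified pairs for one force-field flavor."""

    flavor: str
    entries: tuple[PairLJ, ...]
    offset: float = 0.0

    def pair(self, type_i: str, type_j: str) -> PairLJ:
        for p in self.entries:
            if {p.type_i, p.type_j} == {type_i, type_j}:
                return p
        raise KeyError(f"no pair {type_i}-{type_j} in table for {self.flavor}")


@dataclass(frozen=True)
class ScanGrid:
    """Inclusive arithmetic progression of candidate r_min values (Å)."""

    lo: float
    hi: float
    step: float
    values: tuple[float, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.values)


def load_atom_types(path=None) -> dict[str, AtomType]:
    """Load the atom-type registry from a YAML config.

    Defaults to the packaged table (OL3_CP OR phosphate revision for RNA,
    OL15 OS for DNA).
    """
    if path is None:
        text = resources.files("nbfixtools.data").joinpath("atom_types.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out: dict[str, AtomType] = {}
    for name, rec in raw["atom_types"].items():
        out[name] = AtomType(
            name=name,
            rmin_half=float(rec["rmin_half"]),
            eps=float(rec["eps"]),
            role=str(rec["role"]),
        )
    return out


def combine_lorentz_berthelot(a: AtomType, b: AtomType) -> PairLJ:
    """Unmodified pair parameters from the Lorentz-Berthelot mixing rules.

    r_min is the sum of the two rmin_half contributions and eps the
    geometric mean of the two well depths.
    """
    return PairLJ(
        type_i=a.name,
        type_j=b.name,
        r_min=a.rmin_half + b.rmin_half,
        eps=math.sqrt(a.eps * b.eps),
        origin="combination-rule",
    )


def apply_nbfix(pair: PairLJ, offset: float, *, eps_override: float | None = None) -> PairLJ:
    """Shift a pair's minimum-energy distance by a signed offset.

    The well depth is never touched by the 0BPh correction; an explicit
    ``eps_override`` is accepted only for scanning experiments.
    """
    new_rmin = pair.r_min + offset
    if new_rmin <= 0:
        raise InvalidOffsetError(
            f"offset {offset} drives r_min of {pair.type_i}-{pair.type_j} to "
            f"{new_rmin} <= 0"
        )
    return replace(
        pair,
        r_min=new_rmin,
        eps=pair.eps if eps_override is None else eps_override,
        origin="nbfix",
    )


def lj_energy(pair: PairLJ, r):
    """12-6 Lennard-Jones energy U(r) = eps[(r_min/r)^12 - 2(r_min/r)^6].

    Accepts a scalar or array of distances (Å); returns kcal/mol.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    x6 = (pair.r_min / r) ** 6
    out = pair.eps * (x6 * x6 - 2.0 * x6)
    return float(out) if out.ndim == 0 else out


def build_nbfix_table(
    flavor: str,
    offset: float = -0.25,
    atom_types: dict[str, AtomType] | None = None,
) -> NBfixTable:
    """Build the two-pair NBfix table for a force-field flavor.

    RNA-OL3CP pairs H5-OR and H4-OR; DNA-OL15 pairs H5-OS and H4-OS.
    Because O3' (and O4' in DNA) share the bridging-oxygen atom type,
    their pairs with H8/H6 inherit the same modification; those contacts
    sit farther away and the effect is incidental.
    """
    if flavor not in FLAVORS:
        raise ConfigurationError(
            f"unknown flavor {flavor!r}; expected one of {sorted(FLAVORS)}"
        )
    if atom_types is None:
        atom_types = load_atom_types()
    o_name, o_role = FLAVORS[flavor]
    by_role = {t.role: t for t in atom_types.values()}
    missing = [r for r in (*_DONOR_ROLES, o_role) if r not in by_role]
    if missing:
        raise ConfigurationError(f"atom-type registry lacks roles: {missing}")
    oxy = by_role[o_role]
    entries = []
    for donor_role in _DONOR_ROLES:
        base = combine_lorentz_berthelot(by_role[donor_role], oxy)
        entries.append(apply_nbfix(base, offset) if offset != 0.0 else base)
    return NBfixTable(flavor=flavor, entries=tuple(entries), offset=offset)


def make_scan_grid(lo: float, hi: float, step: float) -> ScanGrid:
    """Inclusive grid lo, lo+step, ..., hi (endpoint within step/2)."""
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if lo >= hi:
        raise ValueError(f"need lo < hi, got {lo} >= {hi}")
    if step >= hi - lo:
        raise ValueError(f"degenerate grid: step {step} >= span {hi - lo}")
    n = int(round((hi - lo) / step))
    values = lo + step * np.arange(n + 1)
    # guard against drift past hi by more than half a step
    values = values[values <= hi + step / 2]
    return ScanGrid(lo=lo, hi=hi, step=step, values=tuple(float(v) for v in values))


# ---------------------------------------------------------------------------
# patch serialization

_AMBER_HEADER = "NBfix_0BPh pairwise vdW override"


def write_patch(table: NBfixTable, dialect: str = "amber") -> str:
    """Serialize a table as an AMBER frcmod LJEDIT block or a GROMACS
    ``[ nonbond_params ]`` override block.

    Round-trips bit-exactly through :func:`read_patch`.
    """
    if dialect == "amber":
        lines = [
            _AMBER_HEADER,
            f"; flavor={table.flavor} offset={table.offset!r}",
            "LJEDIT",
        ]
        for p in table.entries:
            lines.append(
                f"  {p.type_i:<4s} {p.type_j:<4s} {p.r_min:10.4f} {p.eps:10.4f}"
                f"  ; origin={p.origin} r_min={p.r_min!r} eps={p.eps!r}"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"
    if dialect == "gromacs":
        lines = [
            f"; {_AMBER_HEADER}",
            f"; flavor={table.flavor} offset={table.offset!r}",
            "[ nonbond_params ]",
            ";  ai    aj  func      sigma(nm)      eps(kJ/mol)",
        ]
        for p in table.entries:
            sigma_nm = p.r_min * 2 ** (-1 / 6) / 10.0
            eps_kj = p.eps * 4.184
            lines.append(
                f"  {p.type_i:<4s} {p.type_j:<4s}  1  {sigma_nm:.10e}  {eps_kj:.10e}"
                f"  ; origin={p.origin} r_min={p.r_min!r} eps={p.eps!r}"
            )
        return "\n".join(lines) + "\n"
    raise UnsupportedFormatError(f"unknown dialect {dialect!r}")


def read_patch(text: str) -> NBfixTable:
    """Parse a patch written by :func:`write_patch` (either dialect)."""
    flavor, offset = "RNA-OL3CP", 0.0
    entries: list[PairLJ] = []
    for line in io.StringIO(text):
        line = line.rstrip("\n")
        stripped = line.strip().lstrip("; ")
        if stripped.startswith("flavor="):
            fields = dict(tok.split("=", 1) for tok in stripped.split())
            flavor = fields["flavor"]
            offset = float(fields["offset"])
        if ";" in line and "origin=" in line:
            payload = line.split(";", 1)[1]
            fields = dict(tok.split("=", 1) for tok in payload.split())
            ti, tj = line.split(";")[0].split()[:2]
            entries.append(
                PairLJ(
                    type_i=ti,
                    type_j=tj,
                    r_min=float(fields["r_min"]),
                    eps=float(fields["eps"]),
                    origin=fields["origin"],
                )
            )
    return NBfixTable(flavor=flavor, entries=tuple(entries), offset=offset)
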