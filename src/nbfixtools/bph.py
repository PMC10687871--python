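"""Type-0 base-phosphate (0BPh) geometry on structures and ensembles.

The 0BPh interaction is the intranucleotide weak C-H···O hydrogen
bond between the base H8 (purines) or H6 (pyrimidines) and the O5'
bridging phosphate oxygen of the same residue.  It requires the base
in the anti range of the glycosidic torsion chi; in syn the donor
hydrogen points away from the backbone and the contact cannot form.

This module annotates per-residue H···O5' distances, classifies chi
as syn/anti, and computes the Altona-Sundaralingam sugar-pucker
pseudorotation phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import Model, Residue

__all__ = [
    "BPhContact",
    "EnsembleBPhReport",
    "dihedral",
    "chi_dihedral",
    "syn_anti",
    "h_o5_distance",
    "annotate_bph",
    "sugar_pucker_phase",
    "pucker_phase_from_torsions",
    "DEFAULT_FORMED_CUTOFF",
]

#: H···O5' distance (Å) below which an anti residue counts as a formed
#: 0BPh contact; a weak CH···O criterion, configurable.
DEFAULT_FORMED_CUTOFF = 3.2

PURINES = {"A", "G", "DA", "DG", "RA", "RG", "ADE", "GUA"}
PYRIMIDINES = {"C", "U", "T", "DC", "DT", "RC", "RU", "CYT", "URA", "THY"}

#: furanose ring torsions nu0..nu4 as atom-name quadruples
RING_TORSIONS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)


class IncompleteResidueError(KeyError):
    pass


class UndefinedDihedralError(ValueError):
    pass


class UndefinedPhaseError(ValueError):
    pass


@dataclass(frozen=True)
class BPhContact:
    chain: str
    resid: int
    resname: str
    donor: str               # "H8" or "H6"
    distance: float          # H...O5' Å
    chi: float               # degrees in (-180, 180]
    chi_class: str           # "syn" / "anti"
    formed: bool
    terminal: bool = False   # 5'-terminal residue lacking phosphate context


@dataclass
class EnsembleBPhReport:
    """Per-residue distance statistics over the models of an ensemble."""

    n_models: int
    residues: list[dict] = field(default_factory=list)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, right-handed convention,
    range (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb1 < 1e-12:
        raise UndefinedDihedralError("three collinear atoms: dihedral undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1) / nb1
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def _wrap_half_open(ang: float) -> float:
    """Map angle to (-180, 180]."""
    ang = (ang + 180.0) % 360.0 - 180.0
    return 180.0 if ang == -180.0 else ang


def is_purine(resname: str) -> bool:
    return resname.strip().upper() in PURINES


def _atom(res: Residue, name: str):
    try:
        return res.atoms[name]
    except KeyError:
        raise IncompleteResidueError(
            f"residue {res.resname}{res.resid}: missing atom {name!r}"
        ) from None


def chi_dihedral(res: Residue) -> float:
    """Glycosidic torsion chi: O4'-C1'-N9-C4 (purines) or O4'-C1'-N1-C2
    (pyrimidines), degrees in (-180, 180]."""
    if is_purine(res.resname):
        names = ("O4'", "C1'", "N9", "C4")
    else:
        names = ("O4'", "C1'", "N1", "C2")
    coords = [_atom(res, n) for n in names]
    return _wrap_half_open(dihedral(*coords))


def syn_anti(chi: float, *, syn_lo: float = -90.0, syn_hi: float = 90.0) -> str:
    """IUPAC classification: syn for chi in [-90, 90), anti otherwise."""
    return "syn" if syn_lo <= chi < syn_hi else "anti"


def h_o5_distance(res: Residue) -> float:
    """Euclidean distance between the base donor hydrogen (H8/H6) and
    the intranucleotide O5'."""
    donor = "H8" if is_purine(res.resname) else "H6"
    h = np.asarray(_atom(res, donor), dtype=float)
    o = np.asarray(_atom(res, "O5'"), dtype=float)
    return float(np.linalg.norm(h - o))


def _contact(res: Residue, cutoff: float) -> BPhContact:
    donor = "H8" if is_purine(res.resname) else "H6"
    chi = chi_dihedral(res)
    cls = syn_anti(chi)
    terminal = not res.has_phosphate
    d = h_o5_distance(res)
    return BPhContact(
        chain=res.chain,
        resid=res.resid,
        resname=res.resname,
        donor=donor,
        distance=d,
        chi=chi,
        chi_class=cls,
        formed=(d <= cutoff and cls == "anti"),
        terminal=terminal,
    )


def annotate_bph(
    models: list[Model],
    formed_cutoff: float = DEFAULT_FORMED_CUTOFF,
) -> tuple[EnsembleBPhReport, list[list[BPhContact]]]:
    """Annotate 0BPh contacts for every model of an ensemble.

    Returns the per-residue ensemble report (mean/std of the H···O5'
    distance over models, population std) and the per-model contact
    lists.  A contact is *formed* when the distance is within the
    cutoff and the base is anti.
    """
    if not models:
        raise ValueError("empty ensemble")
    per_model: list[list[BPhContact]] = []
    for m in models:
        contacts = []
        for res in m.residues:
            try:
                contacts.append(_contact(res, formed_cutoff))
            except IncompleteResidueError:
                continue
        per_model.append(contacts)
    report = EnsembleBPhReport(n_models=len(models))
    keys = [(c.chain, c.resid, c.resname, c.donor) for c in per_model[0]]
    for i, key in enumerate(keys):
        dists = np.array([pm[i].distance for pm in per_model])
        n_syn = sum(pm[i].chi_class == "syn" for pm in per_model)
        report.residues.append(
            {
                "chain": key[0],
                "resid": key[1],
                "resname": key[2],
                "donor": key[3],
                "mean_distance": float(dists.mean()),
                "std_distance": float(dists.std()),  # population std
                "n_syn": int(n_syn),
                "n_anti": len(per_model) - int(n_syn),
                "n_formed": int(sum(pm[i].formed for pm in per_model)),
            }
        )
    return report, per_model


def pucker_phase_from_torsions(nus) -> tuple[float, str]:
    """Altona-Sundaralingam pseudorotation phase from nu0..nu4 (degrees).

    Returns (P in [0, 360), class) with class C3'-endo for P in [0, 36),
    C2'-endo for P in [144, 180), otherwise 'other'.
    """
    nu = [math.radians(v) for v in nus]
    if len(nu) != 5:
        raise ValueError("need exactly five ring torsions nu0..nu4")
    if all(abs(v) < 1e-10 for v in nu):
        raise UndefinedPhaseError("planar ring: pseudorotation phase undefined")
    num = (nus[4] + nus[1]) - (nus[3] + nus[0])
    den = 2.0 * nus[2] * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))
    if abs(nus[2]) < 1e-10:
        # nu2 ~ 0 means cos P ~ 0: phase is +-90 by the numerator sign
        if abs(num) < 1e-10:
            raise UndefinedPhaseError("degenerate ring torsions")
        p = 90.0 if num > 0 else 270.0
    else:
        p = math.degrees(math.atan(num / den))
        if nus[2] < 0:
            p += 180.0
    p %= 360.0
    if 0.0 <= p < 36.0:
        cls = "C3'-endo"
    elif 144.0 <= p < 180.0:
        cls = "C2'-endo"
    else:
        cls = "other"
    return p, cls


def sugar_pucker_phase(res: Residue) -> tuple[float, str]:
    """Pseudorotation phase of the furanose ring from coordinates."""
    nus = []
    for quad in RING_TORSIONS:
        coords = [_atom(res, n) for n in quad]
        nus.append(dihedral(*coords))
    return pucker_phase_from_torsions(nus)
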