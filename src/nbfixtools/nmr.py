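"""Back-calculation of NMR observables and chi-square agreement scoring.

Four observable classes are scored against a conformational ensemble:

* backbone and sugar 3J scalar couplings via Karplus relations,
  J(theta) = A cos^2(theta+phi) + B cos(theta+phi) + C, averaged
  linearly over frames;
* NOE effective distances via r^-6 ensemble averaging,
  r_eff = (sum_i w_i r_i^-6)^(-1/6);
* ambiguous NOEs, where 2-3 proton pairs contribute to one cross-peak
  and their r^-6 terms are summed per frame before averaging;
* unobserved NOEs (uNOE), the absence of a cross-peak implying
  r_eff >= bound, scored one-sided flat-bottom.

Class chi^2 is the mean squared z-score; the total is the
count-weighted mean over classes, sum(n_i chi2_i) / sum(n_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KarplusCoeffs",
    "KARPLUS_SETS",
    "Restraint",
    "RestraintSet",
    "ChiSquareReport",
    "karplus_j",
    "ensemble_j",
    "noe_reff",
    "amb_noe_reff",
    "unoe_score",
    "class_chi2",
    "total_chi2",
    "back_calculate",
    "score_restraints",
    "read_restraints",
    "write_restraints",
]

RESTRAINT_KINDS = ("J-backbone", "J-sugar", "NOE", "ambNOE", "uNOE")

#: per-class default uncertainties when a restraint carries none
DEFAULT_SIGMA = {"J-backbone": 1.5, "J-sugar": 1.5, "uNOE": 0.5}
DEFAULT_NOE_SIGMA_FRACTION = 0.2


@dataclass(frozen=True)
class KarplusCoeffs:
    """Karplus coefficients A, B, C (Hz) with optional phase shift phi (deg)."""

    label: str
    a: float
    b: float
    c: float
    phase: float = 0.0

    def __post_init__(self):
        if not self.label:
            raise ValueError("Karplus set label must be nonempty")


#: named registry of common nucleic-acid Karplus parameterizations
KARPLUS_SETS = {
    # H-C-O-P backbone couplings (Lankhorst et al. style)
    "HCOP": KarplusCoeffs("HCOP", 15.3, -6.2, 1.5),
    # H-C-C-H ribose couplings (Haasnoot/Altona-type average)
    "HCCH": KarplusCoeffs("HCCH", 9.67, -2.03, 0.0),
}


@dataclass(frozen=True)
class Restraint:
    kind: str
    selector: str                      # dihedral or proton-pair label
    value: float | None = None         # Hz for J, Å for NOE; None for uNOE
    bound: float | None = None         # Å lower bound, uNOE only
    sigma: float | None = None
    group: str | None = None           # ambNOE group id
    pairs: tuple[str, ...] = ()        # ambNOE contributing pair labels
    karplus: str | None = None

    def __post_init__(self):
        if self.kind not in RESTRAINT_KINDS:
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.kind == "uNOE":
            if self.bound is None or self.bound <= 0:
                raise ValueError("uNOE restraint requires a positive lower bound")
        elif self.value is None:
            raise ValueError(f"{self.kind} restraint requires a value")
        if self.kind == "ambNOE" and len(self.pairs) not in (2, 3):
            raise ValueError("ambNOE must combine 2 or 3 proton pairs")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def effective_sigma(self) -> float:
        if self.sigma is not None:
            return self.sigma
        if self.kind in DEFAULT_SIGMA:
            return DEFAULT_SIGMA[self.kind]
        return DEFAULT_NOE_SIGMA_FRACTION * float(self.value)


@dataclass
class RestraintSet:
    restraints: list[Restraint] = field(default_factory=list)

    def by_kind(self, kind: str) -> list[Restraint]:
        return [r for r in self.restraints if r.kind == kind]


@dataclass
class ChiSquareReport:
    per_class: dict[str, float]
    counts: dict[str, int]
    total: float
    n_violations: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"class": k, "chi2": self.per_class[k], "n": self.counts[k]}
            for k in self.per_class
        ]
        rows.append({"class": "total", "chi2": self.total, "n": sum(self.counts.values())})
        return pd.DataFrame(rows)


def karplus_j(theta, coeffs: KarplusCoeffs):
    """3J coupling (Hz) from a dihedral (degrees)."""
    th = np.radians(np.asarray(theta, float) + coeffs.phase)
    c = np.cos(th)
    out = coeffs.a * c * c + coeffs.b * c + coeffs.c
    return float(out) if out.ndim == 0 else out


def _check_weights(weights, n):
    w = np.asarray(weights, float)
    if w.shape[0] != n:
        raise ValueError(f"weight length {w.shape[0]} != frame count {n}")
    return w / w.sum()


def ensemble_j(dihedrals, weights, coeffs: KarplusCoeffs) -> float:
    """Weighted ensemble average of per-frame Karplus couplings.

    J averages linearly over conformers (fast exchange limit).
    """
    dihedrals = np.asarray(dihedrals, float)
    w = _check_weights(weights, dihedrals.shape[0])
    return float(np.sum(w * karplus_j(dihedrals, coeffs)))


def noe_reff(distances, weights) -> float:
    """NOE effective distance (sum_i w_i r_i^-6)^(-1/6) in Å."""
    r = np.asarray(distances, float)
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    w = _check_weights(weights, r.shape[0])
    return float(np.sum(w * r**-6.0) ** (-1.0 / 6.0))


def amb_noe_reff(pair_distances, weights) -> float:
    """Ambiguous-NOE effective distance.

    ``pair_distances`` has shape (n_frames, n_pairs) with 2 or 3 pairs;
    the r^-6 contributions of the pairs are summed within each frame,
    then averaged over frames: (sum_f w_f sum_p r_fp^-6)^(-1/6).
    """
    r = np.asarray(pair_distances, float)
    if r.ndim != 2 or r.shape[1] not in (2, 3):
        raise ValueError("ambNOE needs an (n_frames, 2 or 3) distance array")
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    w = _check_weights(weights, r.shape[0])
    return float(np.sum(w * np.sum(r**-6.0, axis=1)) ** (-1.0 / 6.0))


def unoe_score(r_eff: float, bound: float, sigma: float) -> tuple[bool, float]:
    """One-sided flat-bottom score for an unobserved NOE.

    Violated only when the back-calculated r_eff falls below the bound;
    the penalty is ((bound - r_eff)/sigma)^2.
    """
    if bound <= 0:
        raise ValueError("bound must be positive")
    if r_eff < bound:
        return True, ((bound - r_eff) / sigma) ** 2
    return False, 0.0


def class_chi2(calculated, restraints: list[Restraint]) -> tuple[float, int, int]:
    """Mean squared z-score for one restraint class.

    Returns (chi2, n, n_violations); for valued kinds the violation
    count is 0, for uNOE it counts bound crossings.
    """
    if len(calculated) != len(restraints):
        raise ValueError("one calculated value per restraint required")
    n = len(restraints)
    if n == 0:
        return 0.0, 0, 0
    contribs = []
    n_viol = 0
    for calc, rst in zip(calculated, restraints):
        sigma = rst.effective_sigma()
        if rst.kind == "uNOE":
            violated, contrib = unoe_score(calc, rst.bound, sigma)
            n_viol += violated
            contribs.append(contrib)
        else:
            contribs.append(((calc - rst.value) / sigma) ** 2)
    return float(np.mean(contribs)), n, n_viol


def total_chi2(per_class: dict[str, tuple[float, int, int]]) -> ChiSquareReport:
    """Count-weighted total chi^2 over the nonempty classes."""
    nonempty = {k: v for k, v in per_class.items() if v[1] > 0}
    if not nonempty:
        raise ValueError("all restraint classes are empty")
    total_n = sum(n for _, n, _ in nonempty.values())
    total = sum(chi2 * n for chi2, n, _ in nonempty.values()) / total_n
    return ChiSquareReport(
        per_class={k: v[0] for k, v in nonempty.items()},
        counts={k: v[1] for k, v in nonempty.items()},
        total=float(total),
        n_violations=sum(v[2] for v in nonempty.values()),
    )


# ---------------------------------------------------------------------------
# scoring structural ensembles against restraint sets

def _selector_dihedral(models, selector: str) -> np.ndarray:
    """Per-frame dihedral for a 'ring:<resid>' selector (N1-C2-N3-C4)."""
    from .bph import dihedral  # local import avoids a cycle at module load

    resid = int(selector.split(":", 1)[1])
    out = []
    for m in models:
        res = next(r for r in m.residues if r.resid == resid)
        out.append(dihedral(*(res.atoms[n] for n in ("N1", "C2", "N3", "C4"))))
    return np.asarray(out)


def _selector_distance(models, selector: str) -> np.ndarray:
    """Per-frame distance for an 'ATOM:<i>-ATOM:<j>' selector."""
    left, right = selector.split("-")
    aname, ares = left.split(":")
    bname, bres = right.split(":")
    out = []
    for m in models:
        ra = next(r for r in m.residues if r.resid == int(ares))
        rb = next(r for r in m.residues if r.resid == int(bres))
        out.append(float(np.linalg.norm(ra.atoms[aname] - rb.atoms[bname])))
    return np.asarray(out)


def back_calculate(models, restraint: Restraint, weights=None) -> float:
    """Ensemble-average the observable one restraint refers to."""
    n = len(models)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    if restraint.kind in ("J-backbone", "J-sugar"):
        coeffs = KARPLUS_SETS[restraint.karplus or "HCCH"]
        return ensemble_j(_selector_dihedral(models, restraint.selector), weights, coeffs)
    if restraint.kind in ("NOE", "uNOE"):
        return noe_reff(_selector_distance(models, restraint.selector), weights)
    if restraint.kind == "ambNOE":
        cols = [_selector_distance(models, p) for p in restraint.pairs]
        return amb_noe_reff(np.column_stack(cols), weights)
    raise ValueError(f"unknown restraint kind {restraint.kind!r}")


def score_restraints(models, rset: RestraintSet, weights=None) -> ChiSquareReport:
    """Back-calculate every restraint over an ensemble and report the
    per-class and total chi^2."""
    per_class: dict[str, tuple[float, int, int]] = {}
    for kind in RESTRAINT_KINDS:
        members = rset.by_kind(kind)
        if not members:
            continue
        calc = [back_calculate(models, r, weights) for r in members]
        per_class[kind] = class_chi2(calc, members)
    return total_chi2(per_class)


# ---------------------------------------------------------------------------
# restraint file I/O (CSV)

_COLUMNS = ["kind", "selector", "value", "bound", "sigma", "group", "pairs", "karplus"]


def read_restraints(path) -> RestraintSet:
    """Read a restraint CSV (columns kind, selector, value, bound, sigma,
    group, pairs, karplus; pairs is '|'-separated)."""
    df = pd.read_csv(path, comment="#")
    out = RestraintSet()
    for _, row in df.iterrows():
        def _get(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        pairs = _get("pairs")
        out.restraints.append(
            Restraint(
                kind=str(row["kind"]),
                selector=str(row["selector"]),
                value=None if _get("value") is None else float(_get("value")),
                bound=None if _get("bound") is None else float(_get("bound")),
                sigma=None if _get("sigma") is None else float(_get("sigma")),
                group=None if _get("group") is None else str(_get("group")),
                pairs=tuple(str(pairs).split("|")) if pairs is not None else (),
                karplus=None if _get("karplus") is None else str(_get("karplus")),
            )
        )
    return out


def write_restraints(rset: RestraintSet, path) -> None:
    rows = []
    for r in rset.restraints:
        rows.append(
            {
                "kind": r.kind,
                "selector": r.selector,
                "value": r.value,
                "bound": r.bound,
                "sigma": r.sigma,
                "group": r.group,
                "pairs": "|".join(r.pairs) if r.pairs else None,
                "karplus": r.karplus,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
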