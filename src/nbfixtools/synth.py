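"""Synthetic fixtures with known ground truth for recovery tests.

Three generator families emulate the statistics the analysis stack is
meant to recover:

* two-state conformational ensembles with a prescribed folding free
  energy at a prescribed temperature, carrying per-state eRMSD and
  H···O5' distance distributions so that LJ reweighting genuinely
  shifts the folded population;
* one-dimensional pair-distance ensembles Boltzmann-distributed under
  a given pair LJ potential (inverse-CDF sampling on a fine grid), the
  substrate for reweighting consistency checks;
* restraint sets back-calculated from a reference structure plus
  Gaussian noise, scoring to chi^2 ~ 1 against their generator.

Every generator takes an explicit seed and stores its ground truth in
the returned record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .constants import rt
from .ljparams import PairLJ, lj_energy
from .models import Model
from .nmr import (
    KARPLUS_SETS,
    Restraint,
    RestraintSet,
    karplus_j,
)
from .bph import dihedral, is_purine
from .ermsd import population_from_dg

__all__ = [
    "TwoStateEnsemble",
    "gen_two_state_ensemble",
    "gen_pair_distance_boltzmann",
    "gen_restraint_set",
    "make_helix_model",
]


@dataclass
class TwoStateEnsemble:
    """Synthetic folded/unfolded trajectory with its generating truth."""

    ermsd: np.ndarray                 # per-frame eRMSD to the native reference
    folded: np.ndarray                # ground-truth state per frame
    distances: dict[tuple[str, str], np.ndarray]
    temperature: float
    truth: dict[str, Any] = field(default_factory=dict)


#: state-conditional H8···O5' distance windows (Å): the folded state has
#: the 0BPh contact formed (short), the unfolded state does not
FOLDED_WINDOW = (2.5, 3.6)
UNFOLDED_WINDOW = (4.2, 6.5)


def _boltzmann_cdf(pair: PairLJ, temperature: float, window, n_grid: int = 4001):
    grid = np.linspace(window[0], window[1], n_grid)
    logp = -lj_energy(pair, grid) / rt(temperature)
    logp -= logp.max()
    pdf = np.exp(logp)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    z = cdf[-1]
    return grid, pdf, cdf / z, z


def gen_two_state_ensemble(
    dg_true: float,
    temperature: float = 298.0,
    n_frames: int = 100_000,
    seed: int = 0,
    pair: PairLJ | None = None,
    folded_window=FOLDED_WINDOW,
    unfolded_window=UNFOLDED_WINDOW,
) -> TwoStateEnsemble:
    """Draw a two-state ensemble with prescribed dG_fold.

    Frames are folded with probability p* = 1/(1+exp(dG/kT)).  Folded
    frames get eRMSD ~ U(0.1, 0.6), unfolded ~ U(0.9, 2.0).  The
    tracked H8···O5' (H5-OR) distance is Boltzmann-distributed under
    ``pair`` (default: the combination-rule H5-OR term) within a short
    state-conditional window for folded frames (0BPh formed) and a long
    one for unfolded frames, so reweighting to a modified H5-OR
    potential genuinely shifts the populations; the exact reweighted
    population is available from :func:`two_state_reweight_truth`.
    """
    if n_frames < 100:
        raise ValueError("n_frames < 100: recovery statistics meaningless")
    if pair is None:
        pair = _default_h5_or_pair()
    p_star = population_from_dg(dg_true, temperature)
    if not 0 < p_star < 1:
        raise ValueError("dG/T combination gives a degenerate population")
    rng = np.random.default_rng(seed)
    folded = rng.random(n_frames) < p_star
    e = np.where(
        folded,
        rng.uniform(0.1, 0.6, n_frames),
        rng.uniform(0.9, 2.0, n_frames),
    )
    d = np.empty(n_frames)
    for state, window in ((True, folded_window), (False, unfolded_window)):
        mask = folded == state
        grid, _, cdf, _ = _boltzmann_cdf(pair, temperature, window)
        d[mask] = np.interp(rng.random(mask.sum()), cdf, grid)
    return TwoStateEnsemble(
        ermsd=e,
        folded=folded,
        distances={("H5", "OR"): d},
        temperature=temperature,
        truth={
            "dg": dg_true,
            "temperature": temperature,
            "p": p_star,
            "seed": seed,
            "n_frames": n_frames,
            "pair": pair,
            "folded_window": tuple(folded_window),
            "unfolded_window": tuple(unfolded_window),
        },
    )


def _default_h5_or_pair() -> PairLJ:
    from .ljparams import combine_lorentz_berthelot, load_atom_types

    at = load_atom_types()
    return combine_lorentz_berthelot(at["H5"], at["OR"])


def two_state_reweight_truth(
    p_old: float,
    pair_old: PairLJ,
    pair_new: PairLJ,
    temperature: float = 298.0,
    folded_window=FOLDED_WINDOW,
    unfolded_window=UNFOLDED_WINDOW,
) -> float:
    """Exact folded population after reweighting a two-state ensemble.

    For distances Boltzmann-distributed per state under the old pair
    potential, switching to the new potential multiplies each state's
    statistical weight by the ratio of its configurational partition
    functions over the state window; the new odds follow by quadrature.
    """
    ratios = []
    for window in (folded_window, unfolded_window):
        grid = np.linspace(window[0], window[1], 4001)
        z_old = np.trapezoid(np.exp(-lj_energy(pair_old, grid) / rt(temperature)), grid)
        z_new = np.trapezoid(np.exp(-lj_energy(pair_new, grid) / rt(temperature)), grid)
        ratios.append(z_new / z_old)
    odds = (p_old / (1.0 - p_old)) * ratios[0] / ratios[1]
    return odds / (1.0 + odds)


def gen_pair_distance_boltzmann(
    pair: PairLJ,
    temperature: float,
    n: int,
    seed: int = 0,
    r_lo: float | None = None,
    r_hi: float | None = None,
    n_grid: int = 20_001,
) -> tuple[np.ndarray, dict[str, Any]]:
    """Sample 1-D distances from p(r) ∝ exp(-U(r)/kT) on [r_lo, r_hi].

    Inverse-CDF sampling on a fine grid; the ground-truth record keeps
    the quadrature mean of the density for oracle comparisons.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if r_lo is None:
        r_lo = 0.8 * pair.r_min
    if r_hi is None:
        r_hi = 2.5 * pair.r_min
    if not (r_lo < pair.r_min < r_hi):
        import warnings

        warnings.warn("sampling interval excludes the potential minimum")
    grid = np.linspace(r_lo, r_hi, n_grid)
    logp = -lj_energy(pair, grid) / rt(temperature)
    logp -= logp.max()
    pdf = np.exp(logp)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    samples = np.interp(u, cdf, grid)
    z = np.trapezoid(pdf, grid)
    truth = {
        "mean_r": float(np.trapezoid(grid * pdf, grid) / z),
        "r_lo": r_lo,
        "r_hi": r_hi,
        "seed": seed,
        "temperature": temperature,
    }
    return samples, truth


# ---------------------------------------------------------------------------
# toy structures

# idealized base ring geometry (Å): a planar hexagon of radius 1.39
_HEX = 1.39 * np.column_stack(
    [np.cos(np.radians(60 * np.arange(6) + 90)), np.sin(np.radians(60 * np.arange(6) + 90)), np.zeros(6)]
)


def _base_atoms(resname: str) -> dict[str, np.ndarray]:
    """Planar idealized six-ring; names chosen so frame atoms exist."""
    if is_purine(resname):
        names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    else:
        names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    return {n: _HEX[i].copy() for i, n in enumerate(names)}


def make_helix_model(
    sequence: str = "GACC",
    rise: float = 2.8,
    twist_deg: float = 32.7,
    radius: float = 9.4,
    seed: int | None = None,
    noise: float = 0.0,
) -> Model:
    """Idealized A-form-like single strand of planar bases on a helix.

    Bases are placed with their ring centers on a helix of the given
    radius, rise and twist, ring planes roughly normal to the axis.
    Purely synthetic: a regular, self-consistent substrate for eRMSD
    and restraint generation, not a refined nucleic-acid geometry.
    """
    from .models import Residue

    rng = np.random.default_rng(seed)
    model = Model()
    for i, letter in enumerate(sequence.upper()):
        theta = np.radians(twist_deg * i)
        center = np.array([radius * np.cos(theta), radius * np.sin(theta), rise * i])
        # rotate the planar base about z by theta so bases stack coherently
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        atoms = {}
        for name, xyz in _base_atoms(letter).items():
            pos = rot @ xyz + center
            if noise > 0:
                pos = pos + rng.normal(0.0, noise, 3)
            atoms[name] = pos
        model.residues.append(
            Residue(chain="A", resid=i + 1, resname=letter, atoms=atoms)
        )
    return model


def gen_restraint_set(
    model: Model,
    noise: float = 0.1,
    seed: int = 0,
    karplus_label: str = "HCCH",
) -> tuple[RestraintSet, dict[str, Any]]:
    """Back-calculate J and NOE observables from a structure and emit
    noisy restraints scoring chi^2 ~ 1 in expectation against it.

    J restraints come from ring dihedrals N1-C2-N3-C4 per residue;
    NOE restraints from inter-residue C2-C2 distances; one uNOE bound
    is placed safely below the largest C2-C2 separation.
    """
    rng = np.random.default_rng(seed)
    coeffs = KARPLUS_SETS[karplus_label]
    rset = RestraintSet()
    truth: dict[str, Any] = {"j": {}, "noe": {}, "seed": seed, "noise": noise}

    # sigma tracks the injected noise but keeps a floor, so noiseless
    # restraints score chi^2 -> 0 rather than standardizing to ~1
    sigma_j = max(noise, 0.02)
    for res in model.residues:
        try:
            quad = [res.atoms[n] for n in ("N1", "C2", "N3", "C4")]
        except KeyError:
            continue
        theta = dihedral(*quad)
        j_true = karplus_j(theta, coeffs)
        truth["j"][res.resid] = j_true
        rset.restraints.append(
            Restraint(
                kind="J-sugar",
                selector=f"ring:{res.resid}",
                value=float(j_true + rng.normal(0, noise)),
                sigma=sigma_j,
                karplus=karplus_label,
            )
        )
    sigma_noe = max(noise, 0.02)
    residues = model.residues
    for i in range(len(residues) - 1):
        a, b = residues[i], residues[i + 1]
        if "C2" not in a.atoms or "C2" not in b.atoms:
            continue
        r_true = float(np.linalg.norm(a.atoms["C2"] - b.atoms["C2"]))
        truth["noe"][(a.resid, b.resid)] = r_true
        rset.restraints.append(
            Restraint(
                kind="NOE",
                selector=f"C2:{a.resid}-C2:{b.resid}",
                value=float(r_true + rng.normal(0, noise)),
                sigma=sigma_noe,
            )
        )
    if len(residues) >= 2:
        far = max(
            residues[1:],
            key=lambda r: float(np.linalg.norm(residues[0].atoms["C2"] - r.atoms["C2"])),
        )
        r_far = float(np.linalg.norm(residues[0].atoms["C2"] - far.atoms["C2"]))
        rset.restraints.append(
            Restraint(
                kind="uNOE",
                selector=f"C2:{residues[0].resid}-C2:{far.resid}",
                bound=max(r_far - 1.0, 0.5),
                sigma=0.5,
            )
        )
        truth["unoe_bound"] = max(r_far - 1.0, 0.5)
    return rset, truth
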