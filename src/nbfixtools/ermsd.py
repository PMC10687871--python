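"""eRMSD: a nucleic-acid structural distance from relative base arrangements.

Each nucleobase gets a local orthonormal frame anchored on its
six-membered ring (origin at the C2/C4/C6 centroid, x-axis toward C2,
z-axis normal to the ring plane, right-handed, with the atom order
chosen so that z points to the same base face for purines and
pyrimidines).  For every ordered pair of bases (j, k) the position of
base k's origin is expressed in base j's frame and scaled
anisotropically,

    r~ = (x/a, y/a, z/b),   a = 5 Å, b = 3 Å,

flattening the penalty perpendicular to the base plane (stacking) less
than in-plane (pairing).  Pairs within the scaled cutoff (2.4)
contribute a 4-component G-vector

    gamma = pi |r~| / cutoff
    G = ( sin(gamma) x~/|r~|, sin(gamma) y~/|r~|, sin(gamma) z~/|r~|,
          1 + cos(gamma) ) / gamma

which decays smoothly to zero at the cutoff surface; farther pairs
contribute exactly zero.  The distance between structures A and B over
N residues is

    eRMSD = sqrt( sum_{j != k} |G_A(j,k) - G_B(j,k)|^2 / N ).

Folding analysis: frames with eRMSD to the native reference at or
below a threshold (default 0.7) count as folded, and the two-state
free energy is dG_fold = -k_B T ln(p / (1 - p)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    DEFAULT_FOLD_THRESHOLD,
    ERMSD_A,
    ERMSD_B,
    ERMSD_CUTOFF,
    rt,
)
from .models import Model
from .bph import PURINES

__all__ = [
    "BaseFrame",
    "base_frames",
    "g_vectors",
    "ermsd",
    "classify_folded",
    "dg_from_population",
    "population_from_dg",
    "FoldMetrics",
    "fold_metrics",
]

_RING_ATOMS = ("C2", "C4", "C6")


class IncompleteResidueError(KeyError):
    pass


class IncompatibleStructuresError(ValueError):
    pass


@dataclass
class BaseFrame:
    origin: np.ndarray      # (3,)
    axes: np.ndarray        # (3, 3), rows = x, y, z unit vectors


def base_frames(model: Model) -> list[BaseFrame]:
    """Local orthonormal frame of every nucleobase of a structure."""
    frames = []
    for res in model.residues:
        try:
            c2 = res.atoms["C2"]
            c4 = res.atoms["C4"]
            c6 = res.atoms["C6"]
        except KeyError as exc:
            raise IncompleteResidueError(
                f"residue {res.resname}{res.resid}: missing ring atom {exc}"
            ) from None
        origin = (c2 + c4 + c6) / 3.0
        x = c2 - origin
        x = x / np.linalg.norm(x)
        # order the in-plane vectors so z points to the same face of the
        # base for purines and pyrimidines
        if res.resname.strip().upper() in PURINES:
            z = np.cross(c6 - origin, c4 - origin)
        else:
            z = np.cross(c4 - origin, c6 - origin)
        z = z / np.linalg.norm(z)
        z = z - np.dot(z, x) * x     # enforce orthogonality for puckered rings
        z = z / np.linalg.norm(z)
        y = np.cross(z, x)
        frames.append(BaseFrame(origin=origin, axes=np.vstack([x, y, z])))
    return frames


def _g_from_scaled(rtil: np.ndarray, cutoff: float) -> np.ndarray:
    d = np.linalg.norm(rtil)
    if d >= cutoff or d < 1e-12:
        return np.zeros(4)
    gamma = np.pi * d / cutoff
    return np.array(
        [
            np.sin(gamma) * rtil[0] / d,
            np.sin(gamma) * rtil[1] / d,
            np.sin(gamma) * rtil[2] / d,
            1.0 + np.cos(gamma),
        ]
    ) / gamma


def g_vectors(
    model: Model,
    a: float = ERMSD_A,
    b: float = ERMSD_B,
    cutoff: float = ERMSD_CUTOFF,
) -> np.ndarray:
    """(N, N, 4) array of G-vectors over all ordered base pairs.

    The diagonal and pairs beyond the scaled cutoff are exactly zero.
    """
    frames = base_frames(model)
    n = len(frames)
    out = np.zeros((n, n, 4))
    for j in range(n):
        fj = frames[j]
        for k in range(n):
            if j == k:
                continue
            rel = fj.axes @ (frames[k].origin - fj.origin)
            rtil = np.array([rel[0] / a, rel[1] / a, rel[2] / b])
            out[j, k] = _g_from_scaled(rtil, cutoff)
    return out


def ermsd(
    model_a: Model,
    model_b: Model,
    a: float = ERMSD_A,
    b: float = ERMSD_B,
    cutoff: float = ERMSD_CUTOFF,
) -> float:
    """eRMSD between two structures with identical residue ordering."""
    if len(model_a.residues) != len(model_b.residues):
        raise IncompatibleStructuresError(
            f"residue counts differ: {len(model_a.residues)} vs {len(model_b.residues)}"
        )
    for ra, rb in zip(model_a.residues, model_b.residues):
        if ra.resname != rb.resname:
            raise IncompatibleStructuresError(
                f"residue mismatch: {ra.resname}{ra.resid} vs {rb.resname}{rb.resid}"
            )
    ga = g_vectors(model_a, a, b, cutoff)
    gb = g_vectors(model_b, a, b, cutoff)
    n = len(model_a.residues)
    return float(np.sqrt(np.sum((ga - gb) ** 2) / n))


def classify_folded(series, threshold: float = DEFAULT_FOLD_THRESHOLD) -> np.ndarray:
    """Boolean folded indicator; the boundary value counts as folded."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.asarray(series, float) <= threshold


def dg_from_population(p: float, temperature: float = 298.0) -> float:
    """Two-state folding free energy -k_B T ln(p/(1-p)) in kcal/mol.

    p = 0 or 1 yields +-inf (an explicit signal, not an exception).
    """
    if not 0 <= p <= 1:
        raise ValueError(f"population must be in [0, 1], got {p}")
    if p == 0:
        return float("inf")
    if p == 1:
        return float("-inf")
    return -rt(temperature) * np.log(p / (1.0 - p))


def population_from_dg(dg: float, temperature: float = 298.0) -> float:
    """Native population 1 / (1 + exp(dG / k_B T))."""
    return float(1.0 / (1.0 + np.exp(dg / rt(temperature))))


@dataclass
class FoldMetrics:
    ermsd: np.ndarray
    folded: np.ndarray
    population: float
    population_err: float
    dg: float
    dg_err: float
    temperature: float
    threshold: float


def fold_metrics(
    ermsd_series,
    weights=None,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    temperature: float = 298.0,
    n_blocks: int = 50,
    n_resamples: int = 200,
    rng=None,
) -> FoldMetrics:
    """Native population and two-state dG_fold from an eRMSD series.

    Uncertainty by block bootstrap over contiguous trajectory blocks;
    frames may carry weights (e.g. from bias reweighting).
    """
    from .reweight import block_bootstrap_error  # local: avoid cycle

    series = np.asarray(ermsd_series, float)
    n = len(series)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    folded = classify_folded(series, threshold)
    p = float(np.sum(weights * folded))
    p_err = block_bootstrap_error(folded.astype(float), weights, n_blocks, n_resamples, rng)
    dg = dg_from_population(p, temperature)
    # propagate: d(dG)/dp = -kT / (p(1-p))
    dg_err = rt(temperature) * p_err / (p * (1 - p)) if 0 < p < 1 else float("nan")
    return FoldMetrics(
        ermsd=series,
        folded=folded,
        population=p,
        population_err=p_err,
        dg=dg,
        dg_err=dg_err,
        temperature=temperature,
        threshold=threshold,
    )
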