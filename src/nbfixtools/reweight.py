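"""Exponential reweighting of trajectory ensembles under modified pair LJ terms.

A simulation run with pair parameters *old* can be re-evaluated under
parameters *new* without resimulating: every frame i receives a weight

    w_i  proportional to  b_i * exp(-dU_i / k_B T),

where dU_i is the change in potential energy of the tracked pairs and
b_i an optional base weight carried over from upstream bias reweighting
(e.g. metadynamics).  Accuracy degrades as the parameter excursion
grows; the Kish effective sample size is reported as the reliability
guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import rt
from .ljparams import PairLJ, ScanGrid, apply_nbfix, combine_lorentz_berthelot, lj_energy

__all__ = [
    "FrameEnsemble",
    "ReweightResult",
    "ScanCurve",
    "ReplicaLadder",
    "delta_u_frame",
    "boltzmann_weights",
    "effective_sample_size",
    "reweight_observable",
    "block_bootstrap_error",
    "scan_reweight",
    "effective_temperature",
]

#: points with ESS below this fraction of N are flagged unreliable
ESS_WARN_FRACTION = 0.05


class DegenerateReweightingError(RuntimeError):
    def __init__(self, msg, ess=None):
        super().__init__(msg)
        self.ess = ess


@dataclass
class FrameEnsemble:
    """Per-frame tracked pair distances plus base weights and temperature.

    ``distances`` maps a pair key (type_i, type_j) to an array of one
    distance per frame.  Multiple tracked contacts of the same atom-type
    pair may be supplied as a 2-D (n_frames, n_contacts) array.
    """

    distances: dict[tuple[str, str], np.ndarray]
    temperature: float = 298.0
    base_weights: np.ndarray | None = None

    def __post_init__(self):
        self.distances = {k: np.atleast_1d(np.asarray(v, float)) for k, v in self.distances.items()}
        lens = {v.shape[0] for v in self.distances.values()}
        if len(lens) != 1:
            raise ValueError(f"inconsistent frame counts per pair: {lens}")
        (self.n_frames,) = lens
        for k, v in self.distances.items():
            if np.any(v <= 0):
                raise ValueError(f"non-positive distance for pair {k}")
        if self.base_weights is None:
            self.base_weights = np.full(self.n_frames, 1.0 / self.n_frames)
        else:
            self.base_weights = np.asarray(self.base_weights, float)
            if self.base_weights.shape != (self.n_frames,):
                raise ValueError("base_weights length mismatch")
            if np.any(self.base_weights < 0) or not np.any(self.base_weights > 0):
                raise ValueError("base weights must be >= 0 and not all zero")


@dataclass
class ReweightResult:
    delta_u: np.ndarray
    weights: np.ndarray
    ess: float
    mean: float
    error: float
    reliable: bool = True


@dataclass
class ScanCurve:
    """Observable as a function of the scanned r_min grid."""

    grid: np.ndarray
    mean: np.ndarray
    error: np.ndarray
    ess: np.ndarray
    reliable: np.ndarray
    role: str = "both"


@dataclass(frozen=True)
class ReplicaLadder:
    """REST2 ladder: solute scaling factors lambda, descending from 1."""

    lambdas: tuple[float, ...]
    t_ref: float = 298.0

    def __post_init__(self):
        lam = self.lambdas
        if not lam or lam[0] != 1.0 or any(l2 >= l1 for l1, l2 in zip(lam, lam[1:])):
            raise ValueError("lambdas must start at 1 and decrease strictly")
        if any(not (0 < v <= 1) for v in lam):
            raise ValueError("lambda values must lie in (0, 1]")


def effective_temperature(ladder: ReplicaLadder, replica: int) -> float:
    """Effective solute temperature T_ref / lambda of one replica."""
    lam = ladder.lambdas[replica]
    return ladder.t_ref / lam


def delta_u_frame(
    distances: dict[tuple[str, str], np.ndarray],
    old_pairs: dict[tuple[str, str], PairLJ],
    new_pairs: dict[tuple[str, str], PairLJ],
) -> np.ndarray:
    """Per-frame potential-energy change dU = sum_pairs [U_new - U_old].

    Only the tracked (modified) pairs enter; the rest of the force field
    cancels in the difference.
    """
    if set(old_pairs) != set(new_pairs):
        raise ValueError(
            f"old/new pair sets differ: {sorted(old_pairs)} vs {sorted(new_pairs)}"
        )
    du = None
    for key, r in distances.items():
        if key not in old_pairs:
            continue
        contrib = lj_energy(new_pairs[key], r) - lj_energy(old_pairs[key], r)
        if contrib.ndim > 1:  # several contacts of the same type pair
            contrib = contrib.sum(axis=tuple(range(1, contrib.ndim)))
        du = contrib if du is None else du + contrib
    if du is None:
        raise ValueError("no tracked distance matches the modified pairs")
    return du


def boltzmann_weights(delta_u, temperature, base_weights=None) -> np.ndarray:
    """Normalized frame weights b_i * exp(-dU_i / kT), log-sum-exp safe."""
    delta_u = np.asarray(delta_u, float)
    n = delta_u.shape[0]
    if base_weights is None:
        base_weights = np.full(n, 1.0 / n)
    base_weights = np.asarray(base_weights, float)
    kt = rt(temperature)
    log_w = np.where(base_weights > 0, np.log(np.where(base_weights > 0, base_weights, 1.0)), -np.inf)
    log_w = log_w - delta_u / kt
    shift = np.max(log_w)
    if not np.isfinite(shift):
        raise DegenerateReweightingError("all frame weights vanished", ess=0.0)
    w = np.exp(log_w - shift)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise DegenerateReweightingError("weight normalization failed", ess=0.0)
    return w / total


def effective_sample_size(weights) -> float:
    """Kish effective sample size 1 / sum(w_i^2) of normalized weights."""
    w = np.asarray(weights, float)
    return float(1.0 / np.sum(w * w))


def block_bootstrap_error(
    values,
    weights,
    n_blocks: int = 50,
    n_resamples: int = 200,
    rng=None,
) -> float:
    """Uncertainty of a weighted mean by block bootstrap.

    The trajectory is cut into ``n_blocks`` contiguous blocks (respecting
    time correlation); blocks are resampled with replacement and the
    weighted mean recomputed per resample.  Returns the standard
    deviation over resamples.
    """
    rng = np.random.default_rng(rng)
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    n = len(values)
    n_blocks = min(n_blocks, n)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    blocks = [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]
    estimates = np.empty(n_resamples)
    for k in range(n_resamples):
        pick = rng.integers(0, len(blocks), size=len(blocks))
        v = np.concatenate([values[blocks[j]] for j in pick])
        w = np.concatenate([weights[blocks[j]] for j in pick])
        tot = w.sum()
        estimates[k] = np.average(v, weights=w) if tot > 0 else np.nan
    return float(np.nanstd(estimates))


def reweight_observable(
    values,
    weights,
    n_blocks: int = 50,
    n_resamples: int = 200,
    rng=None,
) -> tuple[float, float]:
    """Weighted mean of a per-frame observable with bootstrap error."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    if values.shape[0] != weights.shape[0]:
        raise ValueError(
            f"length mismatch: {values.shape[0]} values vs {weights.shape[0]} weights"
        )
    mean = float(np.average(values, weights=weights))
    err = block_bootstrap_error(values, weights, n_blocks, n_resamples, rng)
    return mean, err


def _pair_sets_for_grid_point(
    r_value: float,
    role: str,
    atom_types,
    oxy_name: str = "OR",
):
    """Old (combination-rule) and new pair parameter sets for one grid point.

    ``role`` selects which donor type is scanned: "purine" moves H5-O,
    "pyrimidine" moves H4-O, "both" moves the two together keeping the
    0.05 Å spacing set by the rmin_half difference of H5 and H4 (the
    grid value refers to the purine pair).
    """
    by_role = {t.role: t for t in atom_types.values()}
    h5, h4 = by_role["purine-H8"], by_role["pyrimidine-H6"]
    oxy = atom_types[oxy_name]
    old = {
        ("H5", oxy_name): combine_lorentz_berthelot(h5, oxy),
        ("H4", oxy_name): combine_lorentz_berthelot(h4, oxy),
    }
    new = dict(old)
    if role in ("purine", "both"):
        off = r_value - old[("H5", oxy_name)].r_min
        new[("H5", oxy_name)] = apply_nbfix(old[("H5", oxy_name)], off)
        if role == "both":
            new[("H4", oxy_name)] = apply_nbfix(old[("H4", oxy_name)], off)
    elif role == "pyrimidine":
        off = r_value - old[("H4", oxy_name)].r_min
        new[("H4", oxy_name)] = apply_nbfix(old[("H4", oxy_name)], off)
    else:
        raise ValueError(f"unknown role {role!r}")
    return old, new


def scan_reweight(
    ensemble: FrameEnsemble,
    grid: ScanGrid,
    role: str,
    observable,
    atom_types,
    oxy_name: str = "OR",
    rng=None,
    n_blocks: int = 50,
    n_resamples: int = 200,
) -> ScanCurve:
    """Reweight an observable across a grid of candidate r_min values.

    Degenerate points (all weight collapsed) are flagged unreliable and
    reported as NaN; the scan continues.
    """
    if min(grid.values) <= 1.0:
        raise ValueError("grid extends below 1 Å: outside physically sane bounds")
    observable = np.asarray(observable, float)
    rng = np.random.default_rng(rng)
    means, errs, esss, ok = [], [], [], []
    for r_value in grid.values:
        old, new = _pair_sets_for_grid_point(r_value, role, atom_types, oxy_name)
        try:
            du = delta_u_frame(ensemble.distances, old, new)
            w = boltzmann_weights(du, ensemble.temperature, ensemble.base_weights)
            mean, err = reweight_observable(
                observable, w, n_blocks, n_resamples, rng=rng.integers(2**31)
            )
            ess = effective_sample_size(w)
            means.append(mean)
            errs.append(err)
            esss.append(ess)
            ok.append(ess >= ESS_WARN_FRACTION * ensemble.n_frames)
        except DegenerateReweightingError:
            means.append(np.nan)
            errs.append(np.nan)
            esss.append(0.0)
            ok.append(False)
    return ScanCurve(
        grid=np.asarray(grid.values),
        mean=np.asarray(means),
        error=np.asarray(errs),
        ess=np.asarray(esss),
        reliable=np.asarray(ok, bool),
        role=role,
    )
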