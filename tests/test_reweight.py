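"""Boltzmann reweighting: weights, ESS, observables, parameter scans."""

import numpy as np
import pytest

from nbfixtools.constants import KB, rt
from nbfixtools.ljparams import (
    apply_nbfix,
    combine_lorentz_berthelot,
    lj_energy,
    make_scan_grid,
)
from nbfixtools.reweight import (
    FrameEnsemble,
    ReplicaLadder,
    boltzmann_weights,
    delta_u_frame,
    effective_sample_size,
    effective_temperature,
    reweight_observable,
    scan_reweight,
)
from nbfixtools.synth import gen_pair_distance_boltzmann


class TestDeltaU:
    def test_identical_parameters_zero(self, h5_or_pair):
        d = {("H5", "OR"): np.array([2.5, 3.0, 3.5])}
        pairs = {("H5", "OR"): h5_or_pair}
        assert np.all(delta_u_frame(d, pairs, pairs) == 0.0)

    def test_single_pair_closed_form(self, h5_or_pair):
        new = apply_nbfix(h5_or_pair, -0.25)
        r = h5_or_pair.r_min
        got = delta_u_frame(
            {("H5", "OR"): np.array([r])},
            {("H5", "OR"): h5_or_pair},
            {("H5", "OR"): new},
        )
        expected = lj_energy(new, r) - lj_energy(h5_or_pair, r)
        assert got[0] == pytest.approx(expected, abs=1e-12)

    def test_two_pairs_additive(self, atom_types, h5_or_pair):
        h4 = combine_lorentz_berthelot(atom_types["H4"], atom_types["OR"])
        old = {("H5", "OR"): h5_or_pair, ("H4", "OR"): h4}
        new = {k: apply_nbfix(v, -0.1) for k, v in old.items()}
        d5 = {("H5", "OR"): np.array([3.0])}
        d4 = {("H4", "OR"): np.array([3.2])}
        both = {**d5, **d4}
        total = delta_u_frame(both, old, new)
        parts = delta_u_frame(d5, {k: old[k] for k in d5}, {k: new[k] for k in d5}) + \
            delta_u_frame(d4, {k: old[k] for k in d4}, {k: new[k] for k in d4})
        assert total[0] == pytest.approx(parts[0], abs=1e-12)

    def test_pair_set_mismatch(self, h5_or_pair):
        with pytest.raises(ValueError):
            delta_u_frame({("H5", "OR"): np.array([3.0])}, {("H5", "OR"): h5_or_pair}, {})


class TestWeights:
    def test_constant_delta_u_returns_base(self):
        base = np.array([0.1, 0.4, 0.5])
        w = boltzmann_weights(np.full(3, 2.7), 298.0, base)
        assert w == pytest.approx(base, abs=1e-12)

    def test_kbt_ln2_gap_gives_two_thirds(self):
        du = np.array([0.0, KB * 298.0 * np.log(2.0)])
        w = boltzmann_weights(du, 298.0)
        assert w == pytest.approx([2 / 3, 1 / 3], abs=1e-12)

    def test_matches_naive_exponential(self):
        rng = np.random.default_rng(1)
        du = rng.normal(0.0, 1.0, 10)
        w = boltzmann_weights(du, 298.0)
        naive = np.exp(-du / rt(298.0))
        naive /= naive.sum()
        assert w == pytest.approx(naive, abs=1e-10)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_collapse_raises(self):
        from nbfixtools.reweight import DegenerateReweightingError

        with pytest.raises(DegenerateReweightingError):
            boltzmann_weights(np.array([0.0, 1.0]), 298.0, np.array([0.0, 0.0]))


class TestESS:
    @pytest.mark.parametrize(
        "weights,expected",
        [
            (np.full(8, 1 / 8), 8.0),
            (np.array([1.0, 0.0, 0.0]), 1.0),
            (np.array([0.5, 0.25, 0.25]), 1 / 0.375),
        ],
    )
    def test_kish_values(self, weights, expected):
        assert effective_sample_size(weights) == pytest.approx(expected)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        w = rng.random(100)
        w /= w.sum()
        assert 1.0 <= effective_sample_size(w) <= 100.0


class TestObservable:
    def test_uniform_weights_plain_mean(self):
        v = np.arange(10.0)
        mean, _ = reweight_observable(v, np.full(10, 0.1), rng=0)
        assert mean == pytest.approx(v.mean())

    def test_retilted_mixture(self):
        # 60/40 indicator mixture retilted to 50/50
        v = np.array([1.0] * 6 + [0.0] * 4)
        w = np.array([0.5 / 6] * 6 + [0.5 / 4] * 4)
        mean, _ = reweight_observable(v, w, rng=0)
        assert mean == pytest.approx(0.5, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reweight_observable(np.ones(5), np.ones(4) / 4)


class TestEffectiveTemperature:
    def test_reference_replica(self):
        lad = ReplicaLadder(lambdas=(1.0, 0.8), t_ref=298.0)
        assert effective_temperature(lad, 0) == pytest.approx(298.0)

    def test_printed_endpoint(self):
        lad = ReplicaLadder(lambdas=(1.0, 0.59984), t_ref=298.0)
        assert round(effective_temperature(lad, 1)) == 497

    def test_arithmetic(self):
        lad = ReplicaLadder(lambdas=(1.0, 0.5), t_ref=275.0)
        assert effective_temperature(lad, 1) == pytest.approx(550.0)

    def test_bad_ladder(self):
        with pytest.raises(ValueError):
            ReplicaLadder(lambdas=(0.9, 0.5))


class TestScan:
    def _ensemble(self, h5_or_pair, n=4000, seed=5):
        d, _ = gen_pair_distance_boltzmann(h5_or_pair, 298.0, n, seed=seed)
        rng = np.random.default_rng(seed + 1)
        obs = (d < h5_or_pair.r_min).astype(float) + 0.01 * rng.normal(size=n)
        return FrameEnsemble(distances={("H5", "OR"): d}, temperature=298.0), obs

    def test_zero_perturbation_identity(self, atom_types, h5_or_pair):
        ens, obs = self._ensemble(h5_or_pair)
        grid = make_scan_grid(h5_or_pair.r_min - 0.05, h5_or_pair.r_min + 0.05, 0.05)
        curve = scan_reweight(ens, grid, "purine", obs, atom_types, rng=0)
        i = 1  # middle point == unmodified r_min
        assert curve.grid[i] == pytest.approx(h5_or_pair.r_min)
        assert curve.mean[i] == pytest.approx(obs.mean(), rel=1e-12)
        assert curve.ess[i] == pytest.approx(len(obs), rel=1e-12)

    def test_frame_order_invariance(self, atom_types, h5_or_pair):
        ens, obs = self._ensemble(h5_or_pair, n=2000)
        grid = make_scan_grid(2.9, 3.1, 0.1)
        a = scan_reweight(ens, grid, "purine", obs, atom_types, rng=0)
        perm = np.random.default_rng(9).permutation(2000)
        ens2 = FrameEnsemble(
            distances={k: v[perm] for k, v in ens.distances.items()}, temperature=298.0
        )
        b = scan_reweight(ens2, grid, "purine", obs[perm], atom_types, rng=0)
        assert b.mean == pytest.approx(a.mean, abs=1e-10)
        assert b.ess == pytest.approx(a.ess, abs=1e-8)

    def test_both_roles_composition(self, atom_types, h5_or_pair):
        # with only H5-OR distances tracked, the "both" scan must equal the
        # purine-only scan (the H4 term contributes no tracked contacts)
        ens, obs = self._ensemble(h5_or_pair, n=1000)
        grid = make_scan_grid(2.9, 3.1, 0.1)
        a = scan_reweight(ens, grid, "purine", obs, atom_types, rng=0)
        b = scan_reweight(ens, grid, "both", obs, atom_types, rng=0)
        assert b.mean == pytest.approx(a.mean, abs=1e-12)

    def test_reweighting_consistency_oracle(self, atom_types, h5_or_pair):
        """Reweighting A->B reproduces direct sampling under B within 3 SE."""
        n = 100_000
        new_pair = apply_nbfix(h5_or_pair, -0.25)
        r_a, _ = gen_pair_distance_boltzmann(h5_or_pair, 298.0, n, seed=12)
        r_b, truth_b = gen_pair_distance_boltzmann(
            new_pair, 298.0, n, seed=13, r_lo=0.8 * h5_or_pair.r_min, r_hi=2.5 * h5_or_pair.r_min
        )
        du = delta_u_frame(
            {("H5", "OR"): r_a},
            {("H5", "OR"): h5_or_pair},
            {("H5", "OR"): new_pair},
        )
        w = boltzmann_weights(du, 298.0)
        mean_rw, err_rw = reweight_observable(r_a, w, rng=3)
        assert abs(mean_rw - r_b.mean()) < 3 * max(err_rw, 1e-4)
        assert abs(mean_rw - truth_b["mean_r"]) < 3 * max(err_rw, 1e-4)
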