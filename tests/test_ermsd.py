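"""eRMSD metric, two-state thermodynamics and density-peak clustering."""

import numpy as np
import pytest

from conftest import blob_distance_matrix, random_rotation
from nbfixtools.cluster import cluster_density_peaks
from nbfixtools.constants import ERMSD_A, ERMSD_B, ERMSD_CUTOFF
from nbfixtools.ermsd import (
    IncompatibleStructuresError,
    base_frames,
    classify_folded,
    dg_from_population,
    ermsd,
    fold_metrics,
    g_vectors,
    population_from_dg,
)
from nbfixtools.synth import gen_two_state_ensemble, make_helix_model


def brute_force_ermsd(model_a, model_b):
    """Independent pair-loop recomputation of the metric from its
    definition, written without reusing the package's G-vector path."""

    def frame(res):
        c2, c4, c6 = res.atoms["C2"], res.atoms["C4"], res.atoms["C6"]
        o = (c2 + c4 + c6) / 3.0
        x = (c2 - o) / np.linalg.norm(c2 - o)
        purine = res.resname in ("A", "G")
        v1, v2 = ((c6 - o), (c4 - o)) if purine else ((c4 - o), (c6 - o))
        z = np.cross(v1, v2)
        z = z / np.linalg.norm(z)
        z = z - (z @ x) * x
        z = z / np.linalg.norm(z)
        y = np.cross(z, x)
        return o, np.array([x, y, z])

    def g(model):
        frames = [frame(r) for r in model.residues]
        n = len(frames)
        out = np.zeros((n, n, 4))
        for j in range(n):
            oj, aj = frames[j]
            for k in range(n):
                if j == k:
                    continue
                rel = aj @ (frames[k][0] - oj)
                rt = np.array([rel[0] / ERMSD_A, rel[1] / ERMSD_A, rel[2] / ERMSD_B])
                d = np.linalg.norm(rt)
                if d >= ERMSD_CUTOFF or d == 0:
                    continue
                gamma = np.pi * d / ERMSD_CUTOFF
                out[j, k, :3] = np.sin(gamma) * rt / d / gamma
                out[j, k, 3] = (1 + np.cos(gamma)) / gamma
        return out

    ga, gb = g(model_a), g(model_b)
    return np.sqrt(np.sum((ga - gb) ** 2) / len(model_a.residues))


class TestBaseFrames:
    def test_axes_orthonormal(self):
        for f in base_frames(make_helix_model("GACU")):
            assert f.axes @ f.axes.T == pytest.approx(np.eye(3), abs=1e-9)
            assert np.linalg.det(f.axes) == pytest.approx(1.0, abs=1e-9)

    def test_planar_ring_z_normal(self):
        model = make_helix_model("A")
        f = base_frames(model)[0]
        ring = np.array([model.residues[0].atoms[n] for n in ("C2", "C4", "C6")])
        for edge in ring[1:] - ring[0]:
            assert f.axes[2] @ edge == pytest.approx(0.0, abs=1e-9)

    def test_frames_rotate_covariantly(self):
        rng = np.random.default_rng(8)
        model = make_helix_model("GACC", noise=0.05, seed=1)
        rot, t = random_rotation(rng), rng.normal(size=3)
        moved = model.transformed(rot, t)
        for f0, f1 in zip(base_frames(model), base_frames(moved)):
            assert f1.origin == pytest.approx(rot @ f0.origin + t, abs=1e-9)
            assert f1.axes == pytest.approx(f0.axes @ rot.T, abs=1e-9)


class TestErmsd:
    def test_identity_and_symmetry(self):
        a = make_helix_model("GAC", noise=0.0)
        b = make_helix_model("GAC", noise=0.2, seed=3)
        assert ermsd(a, a) == 0.0
        assert ermsd(a, b) == pytest.approx(ermsd(b, a), abs=1e-12)
        assert ermsd(a, b) > 0

    @pytest.mark.parametrize("seq", ["GAC", "GACU"])
    def test_brute_force_equivalence(self, seq):
        a = make_helix_model(seq)
        b = make_helix_model(seq, noise=0.3, seed=7)
        assert ermsd(a, b) == pytest.approx(brute_force_ermsd(a, b), abs=1e-6)

    def test_displaced_base(self):
        a = make_helix_model("GAC")
        b = make_helix_model("GAC")
        for name in b.residues[1].atoms:
            b.residues[1].atoms[name] = b.residues[1].atoms[name] + np.array([1.5, 0, 0])
        assert ermsd(a, b) == pytest.approx(brute_force_ermsd(a, b), abs=1e-6)

    def test_rigid_body_invariance(self):
        rng = np.random.default_rng(11)
        a = make_helix_model("GACU")
        b = make_helix_model("GACU", noise=0.2, seed=2)
        rot, t = random_rotation(rng), rng.normal(size=3)
        assert ermsd(a.transformed(rot, t), b) == pytest.approx(ermsd(a, b), abs=1e-9)

    def test_continuity_under_small_perturbation(self):
        a = make_helix_model("GAC")
        rng = np.random.default_rng(21)
        vals = []
        for eps in (1e-4, 1e-3, 1e-2):
            b = make_helix_model("GAC")
            for res in b.residues:
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + eps * rng.normal(size=3)
            vals.append(ermsd(a, b))
        assert vals[0] < vals[1] < vals[2]
        assert vals[0] < 1e-2

    def test_cutoff_pairs_contribute_zero(self):
        a = make_helix_model("GA", rise=100.0)  # far beyond the ellipsoid cutoff
        g = g_vectors(a)
        assert np.all(g == 0.0)

    def test_residue_mismatch(self):
        with pytest.raises(IncompatibleStructuresError):
            ermsd(make_helix_model("GAC"), make_helix_model("GACU"))


class TestTwoState:
    @pytest.mark.parametrize(
        "series,threshold,expected",
        [((0.2, 0.9, 0.69), 0.7, (True, False, True)), ((0.0, 0.7), 0.7, (True, True))],
    )
    def test_classify_boundary_folded(self, series, threshold, expected):
        assert tuple(classify_folded(series, threshold)) == expected

    def test_dg_zero_at_half(self):
        assert dg_from_population(0.5, 298.0) == pytest.approx(0.0, abs=1e-12)

    def test_printed_population_correspondence(self):
        # 68.3 % native population corresponds to the printed -0.5 kcal/mol
        assert round(dg_from_population(0.683, 298.0), 1) == -0.5

    def test_population_shift_about_24_percent(self):
        shift = population_from_dg(-0.5, 298.0) - population_from_dg(0.1, 298.0)
        assert shift == pytest.approx(0.24, abs=0.01)

    def test_inverse_identity(self):
        for p in (1e-6, 0.3, 0.5, 0.9, 1 - 1e-6):
            back = population_from_dg(dg_from_population(p, 310.0), 310.0)
            assert back == pytest.approx(p, rel=1e-12)

    def test_extreme_populations_signal_infinity(self):
        assert dg_from_population(0.0) == np.inf
        assert dg_from_population(1.0) == -np.inf

    @pytest.mark.parametrize("dg_true", [-1.0, 0.0, 1.0])
    def test_parameter_recovery(self, dg_true):
        ens = gen_two_state_ensemble(dg_true, 298.0, 100_000, seed=17)
        fm = fold_metrics(ens.ermsd, rng=4)
        assert abs(fm.dg - dg_true) < 0.05
        assert fm.dg_err < 0.05


class TestDensityPeaks:
    def test_single_point(self):
        ca = cluster_density_peaks(np.zeros((1, 1)))
        assert ca.n_clusters == 1
        assert ca.populations[0] == pytest.approx(100.0)

    def test_two_blobs_even_split(self):
        ca = cluster_density_peaks(blob_distance_matrix([[0, 0], [10, 0]], 10, seed=0))
        assert ca.n_clusters == 2
        assert sorted(ca.populations) == pytest.approx([50.0, 50.0])

    @pytest.mark.parametrize("k,centers", [
        (1, [[0, 0]]),
        (2, [[0, 0], [10, 0]]),
        (3, [[0, 0], [10, 0], [5, 8.7]]),
    ])
    def test_k_recovery_over_seeds(self, k, centers):
        for seed in range(10):
            ca = cluster_density_peaks(blob_distance_matrix(centers, 10, seed))
            assert ca.n_clusters == k, f"seed {seed}"

    def test_duplicating_points_preserves_clusters(self):
        d = blob_distance_matrix([[0, 0], [10, 0]], 10, seed=1)
        n = d.shape[0]
        dd = np.zeros((2 * n, 2 * n))
        dd[:n, :n] = dd[:n, n:] = dd[n:, :n] = dd[n:, n:] = d
        np.fill_diagonal(dd, 0.0)
        assert cluster_density_peaks(dd).n_clusters == cluster_density_peaks(d).n_clusters

    def test_every_frame_assigned(self):
        ca = cluster_density_peaks(blob_distance_matrix([[0, 0], [8, 8]], 15, seed=2))
        assert np.all(ca.labels >= 0)
        assert ca.populations.sum() == pytest.approx(100.0)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            cluster_density_peaks(m)
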