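import numpy as np
import pytest

from nbfixtools.ljparams import combine_lorentz_berthelot, load_atom_types
from nbfixtools.models import Residue


@pytest.fixture(scope="session")
def atom_types():
    return load_atom_types()


@pytest.fixture(scope="session")
def h5_or_pair(atom_types):
    return combine_lorentz_berthelot(atom_types["H5"], atom_types["OR"])


def dihedral_quad(theta_deg):
    """Four points whose p0-p1-p2-p3 dihedral is exactly theta_deg."""
    th = np.radians(theta_deg)
    return (
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 0.0, 0.0]),
        np.array([0.0, 0.0, 1.0]),
        np.array([np.cos(th), np.sin(th), 1.0]),
    )


def make_nucleotide(resname="A", chi_deg=-160.0, h_o5=2.8, with_phosphate=True):
    """Minimal nucleotide with a prescribed glycosidic torsion and a
    donor hydrogen placed at a prescribed distance from O5'."""
    p0, p1, p2, p3 = dihedral_quad(chi_deg)
    purine = resname in ("A", "G")
    atoms = {
        "O4'": p0,
        "C1'": p1,
        ("N9" if purine else "N1"): p2,
        ("C4" if purine else "C2"): p3,
        ("H8" if purine else "H6"): np.array([5.0, 0.0, 0.0]),
        "O5'": np.array([5.0 + h_o5, 0.0, 0.0]),
    }
    if with_phosphate:
        atoms["P"] = np.array([7.0, 1.0, 0.0])
    return Residue(chain="A", resid=1, resname=resname, atoms=atoms)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def blob_distance_matrix(centers, n_per_blob, seed, scale=0.3):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(c, scale, (n_per_blob, 2)) for c in centers])
    return np.linalg.norm(pts[:, None] - pts[None], axis=-1)
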