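"""Multi-model PDB reading and writing.

Parsing goes through Bio.PDB; structures are converted to the package's
plain :class:`~nbfixtools.models.Model` containers.  Writing emits
standard fixed-width ATOM records (8.3 coordinate fields), so a
write -> read round trip preserves atom names, residue ids and
coordinates at PDB precision.
"""

from __future__ import annotations

import warnings

import numpy as np
from Bio.PDB import PDBParser

from .models import Model, Residue

__all__ = ["read_multimodel_pdb", "write_multimodel_pdb"]


def read_multimodel_pdb(path) -> list[Model]:
    """Read every MODEL of a PDB file into Model containers."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", path)
    models: list[Model] = []
    for bmodel in structure:
        model = Model(serial=bmodel.id + 1)
        for chain in bmodel:
            for res in chain:
                if res.id[0] != " ":  # skip heteroatoms/water
                    continue
                out = Residue(chain=chain.id, resid=res.id[1], resname=res.resname.strip())
                for atom in res:
                    out.atoms[atom.get_name()] = np.asarray(atom.coord, dtype=float)
                model.residues.append(out)
        models.append(model)
    if not models:
        raise ValueError(f"no models parsed from {path}")
    return models


def _element(atom_name: str) -> str:
    stripped = atom_name.strip("0123456789'*")
    return stripped[:1].upper() if stripped else "X"


def write_multimodel_pdb(models: list[Model], path) -> None:
    """Write models as MODEL/ENDMDL blocks of fixed-width ATOM records."""
    with open(path, "w") as fh:
        for i, model in enumerate(models, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            serial = 0
            for res in model.residues:
                for name, xyz in res.atoms.items():
                    serial += 1
                    # PDB columns: name left-shifted for 4-char names
                    aname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
                    fh.write(
                        f"ATOM  {serial:5d} {aname} {res.resname:>3s} {res.chain:1s}"
                        f"{res.resid:4d}    "
                        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {_element(name):>2s}\n"
                    )
            fh.write("ENDMDL\n")
        fh.write("END\n")
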