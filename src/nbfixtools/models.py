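"""Lightweight in-memory structure containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Residue", "Model"]


@dataclass
class Residue:
    """One nucleotide: id plus a name -> xyz (Å) atom mapping."""

    chain: str
    resid: int
    resname: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def has_phosphate(self) -> bool:
        return "P" in self.atoms

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Residue":
        return Residue(
            chain=self.chain,
            resid=self.resid,
            resname=self.resname,
            atoms={
                n: np.asarray(rotation) @ np.asarray(x) + np.asarray(translation)
                for n, x in self.atoms.items()
            },
        )


@dataclass
class Model:
    """One ensemble member (e.g. one MODEL of a multi-model PDB)."""

    residues: list[Residue] = field(default_factory=list)
    serial: int = 1

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Model":
        return Model(
            residues=[r.transformed(rotation, translation) for r in self.residues],
            serial=self.serial,
        )
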