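"""Backbone structure containers shared across the pipeline.

A model is a ``(n_residues, 6, 3)`` coordinate array over the fixed atom
order N, H, CA, CB, C, O (NaN where an atom does not exist, e.g. glycine
CB).  :class:`StructureEnsemble` carries an ordered set of such models with
per-model pseudo-energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry

ATOM_ORDER = ("N", "H", "CA", "CB", "C", "O")
ATOM_INDEX = {name: i for i, name in enumerate(ATOM_ORDER)}

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA1 = {v: k for k, v in AA3.items()}


@dataclass
class Model:
    """One set of backbone coordinates for a chain."""

    coords: np.ndarray  # (n_res, 6, 3)
    sequence: str
    resnums: np.ndarray  # 1-based residue numbers, shape (n_res,)
    pseudo_energy: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.resnums = np.asarray(self.resnums, dtype=int)
        if self.coords.shape != (len(self.sequence), 6, 3):
            raise ValueError("coords shape does not match sequence length")
        self._lookup = {int(r): i for i, r in enumerate(self.resnums)}

    def position(self, resnum: int, atom: str) -> np.ndarray:
        try:
            ri = self._lookup[int(resnum)]
        except KeyError:
            raise KeyError(f"residue {resnum} not in model") from None
        try:
            ai = ATOM_INDEX[atom]
        except KeyError:
            raise KeyError(f"unknown backbone atom {atom!r}") from None
        xyz = self.coords[ri, ai]
        if np.any(np.isnan(xyz)):
            raise KeyError(f"atom {atom} of residue {resnum} is absent")
        return xyz

    def distance(self, res_a: int, atom_a: str, res_b: int, atom_b: str) -> float:
        return float(np.linalg.norm(self.position(res_a, atom_a) - self.position(res_b, atom_b)))


@dataclass
class StructureEnsemble:
    """Ordered set of backbone models for one chain."""

    sequence: str
    resnums: np.ndarray
    models: list[Model] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    h_reconstructed: bool = False

    def __post_init__(self) -> None:
        self.resnums = np.asarray(self.resnums, dtype=int)

    def __len__(self) -> int:
        return len(self.models)

    @property
    def pseudo_energies(self) -> np.ndarray:
        return np.array([np.inf if m.pseudo_energy is None else m.pseudo_energy
                         for m in self.models])

    def sorted_by_energy(self) -> "StructureEnsemble":
        """Stable sort of models by pseudo-energy (ties keep input order)."""
        order = np.argsort(self.pseudo_energies, kind="stable")
        out = StructureEnsemble(self.sequence, self.resnums,
                                [self.models[i] for i in order],
                                dict(self.provenance), self.h_reconstructed)
        return out

    def lowest(self, n: int) -> list[Model]:
        return self.sorted_by_energy().models[:n]


def model_from_backbone(bb: dict[str, np.ndarray], sequence: str,
                        resnums=None) -> Model:
    """Assemble a Model from per-atom coordinate arrays.

    ``bb`` must contain N, CA, C; H, O, CB are built from ideal geometry when
    absent.  Glycine CB is set to NaN.
    """
    n = len(sequence)
    N, CA, C = bb["N"], bb["CA"], bb["C"]
    H = bb.get("H")
    if H is None:
        H = geometry.add_amide_hydrogens(N, CA, C)
    O = bb.get("O")
    if O is None:
        O = geometry.add_carbonyl_oxygens(N, CA, C)
    CB = bb.get("CB")
    if CB is None:
        CB = geometry.add_beta_carbons(N, CA, C)
    coords = np.full((n, 6, 3), np.nan)
    for name, arr in (("N", N), ("H", H), ("CA", CA), ("CB", CB), ("C", C), ("O", O)):
        coords[:, ATOM_INDEX[name], :] = arr
    for i, aa in enumerate(sequence):
        if aa == "G":
            coords[i, ATOM_INDEX["CB"], :] = np.nan
        if aa == "P":
            coords[i, ATOM_INDEX["H"], :] = np.nan  # proline has no amide H
    if resnums is None:
        resnums = np.arange(1, n + 1)
    return Model(coords, sequence, resnums)
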