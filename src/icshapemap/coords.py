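"""Per-residue coordinate models of RNA and PDB I/O.

A :class:`CoordinateModel` stores named-atom 3D coordinates (Angstrom)
indexed by 1-based residue number, plus an optional model energy used to
rank alternative models of the same molecule.  Only the backbone atoms
the distance measurements need (C5' and O3') are required; anything else
present in a PDB file is kept as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


def _normalize_atom(name: str) -> str:
    # legacy PDB dialect uses '*' where modern files use a prime
    return name.strip().replace("*", "'")


@dataclass
class CoordinateModel:
    """Named-atom coordinates per residue, 1-based residue numbering."""

    name: str = "model"
    atoms: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    energy: float | None = None

    def set_atom(self, resid: int, atom: str, xyz) -> None:
        self.atoms[(resid, _normalize_atom(atom))] = np.asarray(xyz, dtype=float)

    def atom(self, resid: int, atom: str) -> np.ndarray:
        key = (resid, _normalize_atom(atom))
        if key not in self.atoms:
            raise KeyError(
                f"model {self.name!r}: residue {resid} has no atom {atom!r}"
            )
        return self.atoms[key]

    @property
    def residues(self) -> list[int]:
        return sorted({r for r, _ in self.atoms})

    def transformed(self, rotation=None, translation=None) -> "CoordinateModel":
        """Return a rigidly moved copy (distances are invariant to this)."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        tra = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        out = CoordinateModel(name=self.name, energy=self.energy)
        for (r, a), xyz in self.atoms.items():
            out.atoms[(r, a)] = rot @ xyz + tra
        return out

    def jittered(self, sigma: float, rng: np.random.Generator) -> "CoordinateModel":
        """Return a copy with isotropic Gaussian coordinate noise (Angstrom)."""
        out = CoordinateModel(name=self.name, energy=self.energy)
        for (r, a), xyz in self.atoms.items():
            out.atoms[(r, a)] = xyz + rng.normal(0.0, sigma, size=3)
        return out


def write_pdb_models(path, models: list[CoordinateModel]) -> None:
    """Write models as a multi-MODEL PDB file.

    Each model's energy (when set) is recorded in a ``REMARK 250 ENERGY``
    line immediately after its MODEL record so round-tripping keeps the
    energy-based ranking.
    """
    with open(path, "w") as fh:
        for imodel, model in enumerate(models, start=1):
            fh.write(f"MODEL     {imodel:>4d}\n")
            if model.energy is not None:
                fh.write(f"REMARK 250 ENERGY {model.energy:.4f}\n")
            serial = 1
            for (resid, atom) in sorted(model.atoms):
                x, y, z = model.atoms[(resid, atom)]
                aname = atom if len(atom) >= 4 else f" {atom:<3s}"
                fh.write(
                    f"ATOM  {serial:>5d} {aname:<4s}   N A{resid:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb_models(path) -> list[CoordinateModel]:
    """Read a (multi-)MODEL PDB file into CoordinateModels.

    Uses Biopython's parser for the coordinates; per-model energies are
    recovered from ``REMARK 250 ENERGY`` lines when present.
    """
    from Bio.PDB import PDBParser

    energies: list[float | None] = []
    current: float | None = None
    seen_model = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                seen_model = True
                current = None
            elif line.startswith("REMARK 250 ENERGY"):
                current = float(line.split()[-1])
            elif line.startswith("ENDMDL"):
                energies.append(current)
    if not seen_model:
        energies = [None]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # placeholder occupancy/element fields
        structure = PDBParser(QUIET=True).get_structure("models", str(path))
    out: list[CoordinateModel] = []
    for imodel, model in enumerate(structure):
        cm = CoordinateModel(
            name=f"model_{imodel + 1}",
            energy=energies[imodel] if imodel < len(energies) else None,
        )
        for chain in model:
            for residue in chain:
                resid = residue.id[1]
                for atom in residue:
                    cm.set_atom(resid, atom.get_name(), atom.get_coord())
        out.append(cm)
    return out
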