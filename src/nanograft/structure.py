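"""Static-structure computations: containers, SASA and residue geometry.

Structures and conformational ensembles wrap biotite's ``AtomArray`` /
``AtomArrayStack`` so that standard PDB I/O and surface-area machinery are
reused; the residue-level quantities layered on top (relative exposure,
side-chain centroids and minimum side-chain distances) are what the
downstream solubility, contact and hotspot analyses consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .errors import EnsembleError

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Theoretical maximum accessible surface areas per residue (Å^2),
#: Tien et al. 2013 ("theoretical" column); used to normalise absolute SASA.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
GENERIC_MAX_SASA = 200.0

#: Residue types counted as hydrophobic for surface analysis.
HYDROPHOBIC_RESIDUES = ("VAL", "ILE", "LEU", "MET", "PHE", "TRP", "TYR")

#: Default relative-SASA threshold above which a residue counts as exposed.
EXPOSURE_THRESHOLD = 0.25

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class Structure:
    """One conformation: a biotite ``AtomArray`` plus residue bookkeeping."""

    def __init__(self, atoms: bst.AtomArray):
        if atoms.array_length() == 0:
            raise ValueError("structure has no atoms")
        if not np.all(np.isfinite(atoms.coord)):
            raise ValueError("structure has non-finite coordinates")
        self.atoms = atoms
        starts = bst.get_residue_starts(atoms)
        self._starts = starts
        self._res_slice = [
            slice(s, e)
            for s, e in zip(starts, list(starts[1:]) + [atoms.array_length()])
        ]
        self.res_ids = atoms.res_id[starts].tolist()
        self.res_names = atoms.res_name[starts].tolist()

    @property
    def n_residues(self) -> int:
        return len(self.res_ids)

    def residue_atoms(self, i: int) -> bst.AtomArray:
        return self.atoms[self._res_slice[i]]

    def residue_coords(self, i: int) -> np.ndarray:
        return self.atoms.coord[self._res_slice[i]]

    def one_letter(self) -> str:
        return "".join(THREE_TO_ONE.get(name, "X") for name in self.res_names)

    def sidechain_mask(self) -> np.ndarray:
        """Atom mask of side-chain heavy atoms; CA stands in for Gly."""
        names = self.atoms.atom_name
        mask = ~np.isin(names, list(BACKBONE_ATOMS))
        for sl, res_name in zip(self._res_slice, self.atoms.res_name[self._starts]):
            if not mask[sl].any():
                sub = names[sl] == "CA"
                mask[sl.start:sl.stop] = sub
        return mask

    def sidechain_coords(self, i: int) -> np.ndarray:
        mask = self.sidechain_mask()[self._res_slice[i]]
        coords = self.atoms.coord[self._res_slice[i]][mask]
        if len(coords) == 0:  # residue of backbone-only atoms without CA
            coords = self.atoms.coord[self._res_slice[i]]
        return coords

    def sidechain_centroids(self) -> np.ndarray:
        """(n_residues, 3) centroid of side-chain heavy atoms (CA for Gly)."""
        return np.array(
            [self.sidechain_coords(i).mean(axis=0) for i in range(self.n_residues)]
        )

    def min_sidechain_distance_matrix(self) -> np.ndarray:
        """Minimum side-chain heavy-atom distance between residue pairs."""
        coords = [self.sidechain_coords(i) for i in range(self.n_residues)]
        n = self.n_residues
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                diff = coords[i][:, None, :] - coords[j][None, :, :]
                d = np.sqrt((diff ** 2).sum(axis=-1)).min()
                out[i, j] = out[j, i] = d
        return out

    def min_heavy_distance_matrix(self) -> np.ndarray:
        """Minimum heavy-atom distance between residue pairs."""
        n = self.n_residues
        out = np.zeros((n, n))
        coords = [self.residue_coords(i) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                diff = coords[i][:, None, :] - coords[j][None, :, :]
                d = np.sqrt((diff ** 2).sum(axis=-1)).min()
                out[i, j] = out[j, i] = d
        return out

    @classmethod
    def from_pdb(cls, path, model: int = 1) -> "Structure":
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=model)
        return cls(atoms[atoms.element != "H"] if "H" in atoms.element else atoms)

    def to_pdb(self, path) -> None:
        pdb = PDBFile()
        pdb.set_structure(self.atoms)
        pdb.write(str(path))


class ConformationEnsemble:
    """N conformations sharing one residue topology (an ``AtomArrayStack``)."""

    def __init__(self, stack: bst.AtomArrayStack):
        if stack.stack_depth() == 0:
            raise EnsembleError("ensemble has no conformations")
        if not np.all(np.isfinite(stack.coord)):
            raise EnsembleError("ensemble has non-finite coordinates")
        self.stack = stack
        self._template = Structure(stack[0])

    @property
    def n_frames(self) -> int:
        return self.stack.stack_depth()

    @property
    def n_residues(self) -> int:
        return self._template.n_residues

    @property
    def res_ids(self):
        return self._template.res_ids

    @property
    def res_names(self):
        return self._template.res_names

    def frame(self, i: int) -> Structure:
        return Structure(self.stack[i])

    def ca_coords(self) -> np.ndarray:
        """(n_frames, n_ca, 3) C-alpha coordinates."""
        mask = self.stack.atom_name == "CA"
        if not mask.any():
            raise EnsembleError("ensemble has no C-alpha atoms")
        return self.stack.coord[:, mask, :]

    @classmethod
    def from_structures(cls, structures) -> "ConformationEnsemble":
        first = structures[0]
        for s in structures[1:]:
            if (
                s.atoms.array_length() != first.atoms.array_length()
                or not np.array_equal(s.atoms.atom_name, first.atoms.atom_name)
                or not np.array_equal(s.atoms.res_id, first.atoms.res_id)
            ):
                raise EnsembleError("conformations do not share one topology")
        stack = bst.stack([s.atoms for s in structures])
        return cls(stack)

    @classmethod
    def from_pdb(cls, path) -> "ConformationEnsemble":
        pdb = PDBFile.read(str(path))
        try:
            stack = pdb.get_structure()
        except Exception as exc:
            raise EnsembleError(
                f"{path}: models do not share one topology ({exc})"
            ) from exc
        return cls(stack)

    def to_pdb(self, path) -> None:
        pdb = PDBFile()
        pdb.set_structure(self.stack)
        pdb.write(str(path))


@dataclass(frozen=True)
class SasaResult:
    """Per-residue absolute (Å^2) and relative solvent accessibility."""

    res_ids: tuple[int, ...]
    res_names: tuple[str, ...]
    absolute: np.ndarray
    relative: np.ndarray


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    point_number: int = 960,
) -> SasaResult:
    """Per-residue solvent-accessible surface area.

    Atom-level SASA comes from biotite's numerical surface sampling
    (Shrake-Rupley-class algorithm, ``point_number`` sphere points, single
    per-element van-der-Waals radii so that pseudo-atom structures are
    accepted); residue SASA is the sum over the residue's atoms.  Relative
    SASA divides by a tabulated per-residue-type maximum, clipped to
    [0, 1.5]; unknown residue types fall back to a generic maximum with a
    warning.
    """
    atoms = structure.atoms
    atom_sasa = bst.sasa(
        atoms,
        probe_radius=probe_radius,
        point_number=point_number,
        vdw_radii="Single",
    )
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    absolute = np.array(
        [atom_sasa[sl].sum() for sl in structure._res_slice]
    )
    maxima = []
    unknown = set()
    for name in structure.res_names:
        if name in MAX_SASA:
            maxima.append(MAX_SASA[name])
        else:
            unknown.add(name)
            maxima.append(GENERIC_MAX_SASA)
    if unknown:
        warnings.warn(
            f"unknown residue type(s) {sorted(unknown)}: using generic "
            f"maximum SASA {GENERIC_MAX_SASA} Å^2",
            stacklevel=2,
        )
    relative = np.clip(absolute / np.array(maxima), 0.0, 1.5)
    return SasaResult(
        tuple(structure.res_ids),
        tuple(structure.res_names),
        absolute,
        relative,
    )


def hydrophobic_exposed(
    structure: Structure,
    rel_sasa_threshold: float = EXPOSURE_THRESHOLD,
    hydrophobic_set: tuple[str, ...] = HYDROPHOBIC_RESIDUES,
    sasa: SasaResult | None = None,
) -> list[int]:
    """Residue indices that are hydrophobic and solvent-exposed.

    A residue qualifies when its type is in ``hydrophobic_set`` and its
    relative SASA is at least ``rel_sasa_threshold``.
    """
    if sasa is None:
        sasa = compute_sasa(structure)
    return [
        i
        for i, (name, rel) in enumerate(zip(sasa.res_names, sasa.relative))
        if name in hydrophobic_set and rel >= rel_sasa_threshold
    ]
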