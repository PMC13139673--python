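"""Hierarchical data model for macromolecular structures and ligand poses.

The containers are deliberately plain: chains hold residues in author
numbering, residues hold atoms, and every atom carries the B-factor channel,
which for predicted models stores the per-atom (or per-residue) pLDDT
confidence on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: one-letter codes for the standard amino acids (three-letter keys).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Atom:
    """One atom: name, element, Cartesian coordinates (Å) and the B-value.

    For AlphaFold-style predicted models ``bvalue`` is the pLDDT confidence;
    for experimental structures it is the crystallographic B-factor.
    """

    name: str
    element: str
    coords: np.ndarray
    bvalue: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """A residue in author numbering, holding an ordered list of atoms."""

    number: int
    aa_code: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.aa_code}{self.number} has no atom {name!r}")

    @property
    def label(self) -> str:
        return f"{self.aa_code}{self.number}{self.insertion_code}"


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"chain {self.id} has no residue {number}{insertion_code}")

    def has_residue(self, number: int, insertion_code: str = "") -> bool:
        try:
            self.residue(number, insertion_code)
            return True
        except KeyError:
            return False


@dataclass
class StructureModel:
    """A parsed structure: chains of residues of atoms plus free metadata.

    ``metadata["experimental"]`` marks models whose B-factor channel is a
    crystallographic B-factor rather than pLDDT; confidence operations
    refuse to run on such models. Model-level scores shipped with predicted
    structures (pTM, ipTM, mean pLDDT) may be carried in ``metadata`` but
    are never computed here.
    """

    id: str
    chains: list[Chain] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"model {self.id}: duplicate chain ids {ids}")

    @property
    def is_experimental(self) -> bool:
        return bool(self.metadata.get("experimental", False))

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"model {self.id} has no chain {chain_id!r}")

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def iter_atoms(self):
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a


@dataclass
class LigandPose:
    """A small-molecule pose: ordered atoms and an optional bond list."""

    label: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"ligand pose {self.label!r} has no atoms")
        if self.bonds is not None:
            n = len(self.atoms)
            for i, j in self.bonds:
                if not (0 <= i < n and 0 <= j < n):
                    raise ValueError(f"pose {self.label}: bond ({i}, {j}) out of range")

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        return np.array([a.coords for a in atoms], dtype=float)

    def elements(self, heavy_only: bool = False) -> list[str]:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        return [a.element for a in atoms]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]
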