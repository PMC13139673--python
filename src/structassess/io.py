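"""Reading and writing structures (PDB/mmCIF via gemmi) and ligands (SDF/PDB).

Predicted-model conventions: the B-factor column carries pLDDT, alternate
locations keep the highest-occupancy conformer (tie broken toward altloc
'A'), and elements missing from the file are inferred from atom names.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import gemmi
import numpy as np

from .model import Atom, Chain, LigandPose, Residue, StructureModel, THREE_TO_ONE

# PDB fixed-width coordinate field: %8.3f
_PDB_COORD_MIN = -999.999
_PDB_COORD_MAX = 9999.999

# Fallback element inference for files without an element column. Standard
# protein atom names: first character after stripping digits, except
# explicit two-letter cases.
_TWO_LETTER = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "SE", "CA2"}


def infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    stripped = name.lstrip("0123456789")
    if stripped[:2].upper() in _TWO_LETTER and len(stripped) >= 2:
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def _coor_format(fmt: str) -> gemmi.CoorFormat:
    return {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[fmt]


def _pick_altloc(group: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties resolve to the alphabetically first altloc."""
    return min(group, key=lambda a: (-a.occ, a.altloc or "~"))


def read_structure(path: str | os.PathLike, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records are kept (hydrogens included); for alternate
    locations only the highest-occupancy conformer of each atom is retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_coor_format(format))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise ValueError(f"{path}: no atoms found")

    gm = st[0]
    chains: list[Chain] = []
    for gchain in gm:
        residues: list[Residue] = []
        for gres in gchain:
            icode = gres.seqid.icode.strip()
            if icode:
                warnings.warn(
                    f"{path.name}: residue {gres.name}{gres.seqid.num} has insertion "
                    f"code {icode!r}; predicted models are expected without them",
                    stacklevel=2,
                )
            # group altlocs by atom name, keep one conformer per name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for ga in gres:  # preserve file order of first occurrence
                group = by_name.pop(ga.name, None)
                if group is None:
                    continue
                chosen = _pick_altloc(group)
                element = chosen.element.name
                if element in ("X", ""):
                    element = infer_element(chosen.name)
                atoms.append(
                    Atom(
                        name=chosen.name,
                        element=element,
                        coords=np.array([chosen.pos.x, chosen.pos.y, chosen.pos.z]),
                        bvalue=chosen.b_iso,
                        occupancy=min(max(chosen.occ, 0.0), 1.0),
                        altloc=chosen.altloc.strip() if chosen.altloc else "",
                        is_hetero=gres.het_flag == "H",
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        number=gres.seqid.num,
                        aa_code=THREE_TO_ONE.get(gres.name, gres.name),
                        atoms=atoms,
                        insertion_code=icode,
                    )
                )
        if residues:
            chains.append(Chain(id=gchain.name, residues=residues))
    if not chains:
        raise ValueError(f"{path}: no residues with atoms")
    return StructureModel(id=path.stem, chains=chains)


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = _residue_name(res)
            gr.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gr.het_flag = "H" if (res.atoms and res.atoms[0].is_hetero) else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.b_iso = atom.bvalue
                ga.occ = atom.occupancy
                if atom.altloc:
                    ga.altloc = atom.altloc
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def _residue_name(res: Residue) -> str:
    from .model import ONE_TO_THREE

    if len(res.aa_code) == 1 and res.aa_code in ONE_TO_THREE:
        return ONE_TO_THREE[res.aa_code]
    return res.aa_code


def write_structure(model: StructureModel, path: str | os.PathLike, format: str = "pdb") -> None:
    """Write a model as PDB or mmCIF; PDB coordinates must fit %8.3f fields."""
    path = Path(path)
    if format == "pdb":
        for _, _, atom in model.iter_atoms():
            if np.any(atom.coords < _PDB_COORD_MIN) or np.any(atom.coords > _PDB_COORD_MAX):
                raise ValueError(
                    f"atom {atom.name}: coordinate {atom.coords} exceeds the "
                    f"PDB fixed-width field range [{_PDB_COORD_MIN}, {_PDB_COORD_MAX}]"
                )
        _to_gemmi(model).write_pdb(str(path))
    elif format == "mmcif":
        _to_gemmi(model).make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_ligand(path: str | os.PathLike, format: str = "auto") -> LigandPose:
    """Read a single-molecule ligand pose from SDF (with bonds) or PDB."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "sdf" if path.suffix.lower() in (".sdf", ".mol", ".sd") else "pdb"
    if format == "sdf":
        return _read_ligand_sdf(path)
    if format == "pdb":
        return _read_ligand_pdb(path)
    raise ValueError(f"unknown ligand format {format!r}")


def _read_ligand_sdf(path: Path) -> LigandPose:
    from rdkit import Chem

    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        mols = [m for m in supplier if m is not None]
    except OSError as exc:
        raise ValueError(f"{path}: cannot parse SDF: {exc}") from exc
    if len(mols) == 0:
        raise ValueError(f"{path}: no molecule parsed from SDF")
    if len(mols) > 1:
        raise ValueError(
            f"{path}: SDF contains {len(mols)} molecules; extract the record "
            "you want into a single-molecule file first"
        )
    mol = mols[0]
    conf = mol.GetConformer()
    atoms = []
    for rd_atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(rd_atom.GetIdx())
        symbol = rd_atom.GetSymbol()
        if not symbol or symbol == "*":
            raise ValueError(f"{path}: atom {rd_atom.GetIdx()} has no element")
        atoms.append(
            Atom(
                name=f"{symbol}{rd_atom.GetIdx() + 1}",
                element=symbol,
                coords=np.array([pos.x, pos.y, pos.z]),
                is_hetero=True,
            )
        )
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else path.stem
    return LigandPose(label=name, atoms=atoms, bonds=bonds or None)


def _read_ligand_pdb(path: Path) -> LigandPose:
    model = read_structure(path, format="pdb")
    atoms = [atom for _, _, atom in model.iter_atoms()]
    return LigandPose(label=path.stem, atoms=atoms, bonds=None)


def write_ligand_pdb(pose: LigandPose, path: str | os.PathLike) -> None:
    """Write a pose as a PDB HETATM block (no bonds)."""
    res = Residue(number=1, aa_code="LIG", atoms=pose.atoms)
    for a in res.atoms:
        a.is_hetero = True
    model = StructureModel(id=pose.label, chains=[Chain(id="X", residues=[res])])
    write_structure(model, path, format="pdb")


def write_ligand_sdf(pose: LigandPose, path: str | os.PathLike) -> None:
    """Write a pose as SDF V2000, including bonds when present."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    for atom in pose.atoms:
        mol.AddAtom(Chem.Atom(atom.element))
    for i, j in pose.bonds or []:
        mol.AddBond(i, j, Chem.BondType.SINGLE)
    conf = Chem.Conformer(len(pose.atoms))
    for idx, atom in enumerate(pose.atoms):
        conf.SetAtomPosition(idx, Point3D(*map(float, atom.coords)))
    mol.AddConformer(conf)
    mol.SetProp("_Name", pose.label)
    with Chem.SDWriter(str(path)) as writer:
        writer.SetKekulize(False)
        writer.write(mol)
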