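"""Geometric protein-ligand contact detection and key-residue fingerprints.

Re-implements the profiling step usually delegated to interaction-profiler
web services, with explicit geometric criteria so runs are reproducible
and tunable:

* hydrogen bond (HB): donor-acceptor heavy-atom distance <= 3.6 Å, and a
  D-H...A angle >= 100 deg when explicit hydrogens are available;
* salt bridge (SB): <= 5.5 Å between oppositely charged centers
  (Lys NZ / Arg guanidinium / His ring N+ versus carboxylate or phosphate
  oxygens, and vice versa);
* hydrophobic contact (HI): apolar carbon-carbon distance <= 4.0 Å;
* π-stacking (PI_STACK): aromatic ring centroids <= 5.5 Å apart with an
  interplanar angle <= 30 deg (parallel) or 60-90 deg (T-shaped).

Detected contacts are collapsed per (residue, kind) keeping the shortest,
then tabulated against a binding site's key residues into the familiar
per-residue code table (HB / SB / HI / π-s, em-dash for none).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .confidence import SiteDefinition
from .model import LigandPose, StructureModel

KIND_CODES = {"HB": "HB", "SB": "SB", "HI": "HI", "PI_STACK": "π-s"}
NO_CONTACT = "—"

COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "P": 1.07, "S": 1.05,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
}


@dataclass
class InteractionRule:
    kind: str
    distance_max: float
    angle_min: float | None = None
    angle_max: float | None = None

    def __post_init__(self) -> None:
        if self.distance_max <= 0:
            raise ValueError("distance_max must be positive")
        for a in (self.angle_min, self.angle_max):
            if a is not None and not 0 <= a <= 180:
                raise ValueError("angle bounds must lie in [0, 180] degrees")


DEFAULT_RULES: dict[str, InteractionRule] = {
    "HB": InteractionRule("HB", distance_max=3.6, angle_min=100.0),
    "SB": InteractionRule("SB", distance_max=5.5),
    "HI": InteractionRule("HI", distance_max=4.0),
    "PI_STACK": InteractionRule("PI_STACK", distance_max=5.5),
}
PI_PARALLEL_MAX = 30.0   # deg
PI_TSHAPE_MIN = 60.0     # deg
PI_TSHAPE_MAX = 90.0     # deg


@dataclass
class InteractionRecord:
    kind: str
    chain_id: str
    residue_number: int
    aa_code: str
    protein_atoms: tuple[str, ...]
    ligand_atoms: tuple[int, ...]
    distance: float
    angle: float | None = None

    @property
    def residue_label(self) -> str:
        return f"{self.aa_code}{self.residue_number}"


@dataclass
class FingerprintReport:
    site_name: str
    rows: list[tuple[str, frozenset[str]]]    # key-residue label -> kinds found

    @property
    def n_key_hit(self) -> int:
        return sum(1 for _, kinds in self.rows if kinds)

    def codes(self) -> list[tuple[str, str]]:
        """Rows rendered with the table code set (HB, SB, HI, π-s, —)."""
        out = []
        for label, kinds in self.rows:
            if kinds:
                order = ["HB", "SB", "HI", "PI_STACK"]
                text = ", ".join(KIND_CODES[k] for k in order if k in kinds)
            else:
                text = NO_CONTACT
            out.append((label, text))
        return out


# --- protein atom chemistry (standard residues, heavy atoms) -------------

_BACKBONE_DONOR = ("N",)
_BACKBONE_ACCEPTOR = ("O", "OXT")

SIDECHAIN_DONORS = {
    "R": ("NE", "NH1", "NH2"), "N": ("ND2",), "Q": ("NE2",), "H": ("ND1", "NE2"),
    "K": ("NZ",), "S": ("OG",), "T": ("OG1",), "W": ("NE1",), "Y": ("OH",),
}
SIDECHAIN_ACCEPTORS = {
    "D": ("OD1", "OD2"), "E": ("OE1", "OE2"), "N": ("OD1",), "Q": ("OE1",),
    "H": ("ND1", "NE2"), "S": ("OG",), "T": ("OG1",), "Y": ("OH",),
}
POSITIVE_CENTERS = {"K": ("NZ",), "R": ("CZ",), "H": ("ND1", "NE2")}
NEGATIVE_CENTERS = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}
APOLAR_CARBONS = {
    "A": ("CB",), "V": ("CB", "CG1", "CG2"), "L": ("CB", "CG", "CD1", "CD2"),
    "I": ("CB", "CG1", "CG2", "CD1"), "P": ("CB", "CG", "CD"),
    "F": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "M": ("CB", "CG", "CE"), "W": ("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "Y": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "K": ("CB", "CG", "CD"), "R": ("CB", "CG"), "T": ("CG2",),
    "Q": ("CB", "CG"), "E": ("CB", "CG"), "D": ("CB",), "N": ("CB",),
    "H": ("CB",), "C": ("CB",),
}
AROMATIC_RINGS = {
    "F": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "Y": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "W": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "H": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


# --- ligand perception ---------------------------------------------------

def infer_bonds(pose: LigandPose, tolerance: float = 1.25) -> list[tuple[int, int]]:
    """Bond inference by covalent-radius distance (<= tolerance * r_i + r_j)."""
    coords = np.array([a.coords for a in pose.atoms])
    elements = [a.element.upper() for a in pose.atoms]
    bonds = []
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            ri = COVALENT_RADII.get(elements[i])
            rj = COVALENT_RADII.get(elements[j])
            if ri is None or rj is None:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= tolerance * (ri + rj):
                bonds.append((i, j))
    return bonds


def _bond_graph(pose: LigandPose) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(pose.atoms)))
    g.add_edges_from(pose.bonds if pose.bonds else infer_bonds(pose))
    return g


@dataclass
class LigandChemistry:
    """Perceived atom classes of a pose: donors, acceptors, charges, rings."""

    donors: list[int] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    positive: list[int] = field(default_factory=list)
    negative: list[int] = field(default_factory=list)
    apolar: list[int] = field(default_factory=list)
    rings: list[list[int]] = field(default_factory=list)
    hydrogen_of: dict[int, list[int]] = field(default_factory=dict)


def perceive_ligand(
    pose: LigandPose, charges: dict[int, int] | None = None
) -> LigandChemistry:
    """Classify ligand atoms from element + bond topology.

    Phosphate and carboxylate oxygens are treated as negatively charged;
    nitrogens with four neighbors as positively charged. An explicit
    ``charges`` mapping (atom index -> formal charge) overrides inference.
    Rings come from the cycle basis of the bond graph; 5-6-membered C/N
    rings that are planar (<= 0.15 Å deviation) count as aromatic.
    """
    g = _bond_graph(pose)
    elements = [a.element.upper() for a in pose.atoms]
    coords = np.array([a.coords for a in pose.atoms])
    chem = LigandChemistry()
    has_h = "H" in elements

    for i, el in enumerate(elements):
        nbrs = list(g.neighbors(i))
        nbr_el = [elements[j] for j in nbrs]
        if el == "H":
            continue
        if el in ("N", "O"):
            chem.acceptors.append(i)
            h_nbrs = [j for j in nbrs if elements[j] == "H"]
            if h_nbrs:
                chem.donors.append(i)
                chem.hydrogen_of[i] = h_nbrs
            elif not has_h:
                chem.donors.append(i)  # protonation unknown: allow as donor
        if el == "C" and nbrs and all(e in ("C", "H") for e in nbr_el):
            chem.apolar.append(i)
        # charge inference
        if charges is not None and i in charges:
            if charges[i] > 0:
                chem.positive.append(i)
            elif charges[i] < 0:
                chem.negative.append(i)
            continue
        if el == "O" and any(e == "P" for e in nbr_el):
            chem.negative.append(i)
        elif el == "O":
            for j in nbrs:
                if elements[j] == "C":
                    o_count = sum(1 for k in g.neighbors(j) if elements[k] == "O")
                    if o_count >= 2:
                        chem.negative.append(i)  # carboxylate-like oxygen
                        break
        if el == "N" and len(nbrs) >= 4:
            chem.positive.append(i)

    for ring in nx.cycle_basis(g):
        if len(ring) not in (5, 6):
            continue
        if not all(elements[i] in ("C", "N") for i in ring):
            continue
        pts = coords[ring]
        if _planarity(pts) <= 0.15:
            chem.rings.append(sorted(ring))
    return chem


def _planarity(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    return float(np.linalg.svd(centered, compute_uv=False)[-1] / np.sqrt(len(points)))


def _ring_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    return centroid, vt[2]


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b, degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# --- detection -----------------------------------------------------------

def detect_interactions(
    protein: StructureModel,
    ligand: LigandPose,
    rules: dict[str, InteractionRule] | None = None,
    ligand_charges: dict[int, int] | None = None,
) -> list[InteractionRecord]:
    """Sweep residue/ligand atom pairs and record geometric contacts.

    Deterministic: records are sorted by (chain, residue, kind, distance)
    and collapsed to the shortest contact per (residue, kind).
    """
    rules = {**DEFAULT_RULES, **(rules or {})}
    chem = perceive_ligand(ligand, charges=ligand_charges)
    if not chem.rings and "PI_STACK" in rules:
        warnings.warn(
            f"ligand {ligand.label}: no aromatic ring perceived; "
            "π-stacking detection skipped",
            stacklevel=2,
        )
    lig_coords = np.array([a.coords for a in ligand.atoms])
    candidates: list[InteractionRecord] = []
    for chain in protein.chains:
        for res in chain.residues:
            if res.atoms and res.atoms[0].is_hetero:
                continue
            candidates.extend(
                _residue_contacts(chain.id, res, ligand, lig_coords, chem, rules)
            )
    return _dedupe(candidates)


def _residue_contacts(chain_id, res, ligand, lig_coords, chem, rules):
    records = []
    atom_by_name = {a.name: a for a in res.atoms}
    aa = res.aa_code

    def rec(kind, patoms, latoms, dist, angle=None):
        records.append(
            InteractionRecord(
                kind=kind, chain_id=chain_id, residue_number=res.number,
                aa_code=aa, protein_atoms=tuple(patoms), ligand_atoms=tuple(latoms),
                distance=float(dist), angle=angle,
            )
        )

    # hydrogen bonds -----------------------------------------------------
    if "HB" in rules:
        rule = rules["HB"]
        donors = _BACKBONE_DONOR + SIDECHAIN_DONORS.get(aa, ())
        acceptors = _BACKBONE_ACCEPTOR + SIDECHAIN_ACCEPTORS.get(aa, ())
        for dname in donors:
            datom = atom_by_name.get(dname)
            if datom is None:
                continue
            for j in chem.acceptors:
                d = np.linalg.norm(datom.coords - lig_coords[j])
                if d > rule.distance_max:
                    continue
                ang = _donor_angle(res, datom, lig_coords[j])
                if ang is not None and rule.angle_min is not None and ang < rule.angle_min:
                    continue
                rec("HB", (dname,), (j,), d, ang)
        for aname in acceptors:
            aatom = atom_by_name.get(aname)
            if aatom is None:
                continue
            for j in chem.donors:
                d = np.linalg.norm(aatom.coords - lig_coords[j])
                if d > rule.distance_max:
                    continue
                ang = _ligand_donor_angle(ligand, chem, j, aatom.coords)
                if ang is not None and rule.angle_min is not None and ang < rule.angle_min:
                    continue
                rec("HB", (aname,), (j,), d, ang)

    # salt bridges -------------------------------------------------------
    if "SB" in rules:
        rule = rules["SB"]
        for pname in POSITIVE_CENTERS.get(aa, ()):
            patom = atom_by_name.get(pname)
            if patom is None:
                continue
            for j in chem.negative:
                d = np.linalg.norm(patom.coords - lig_coords[j])
                if d <= rule.distance_max:
                    rec("SB", (pname,), (j,), d)
        for nname in NEGATIVE_CENTERS.get(aa, ()):
            natom = atom_by_name.get(nname)
            if natom is None:
                continue
            for j in chem.positive:
                d = np.linalg.norm(natom.coords - lig_coords[j])
                if d <= rule.distance_max:
                    rec("SB", (nname,), (j,), d)

    # hydrophobic contacts -----------------------------------------------
    if "HI" in rules:
        rule = rules["HI"]
        for cname in APOLAR_CARBONS.get(aa, ()):
            catom = atom_by_name.get(cname)
            if catom is None:
                continue
            for j in chem.apolar:
                d = np.linalg.norm(catom.coords - lig_coords[j])
                if d <= rule.distance_max:
                    rec("HI", (cname,), (j,), d)

    # π-stacking ----------------------------------------------------------
    if "PI_STACK" in rules and chem.rings:
        rule = rules["PI_STACK"]
        ring_names = AROMATIC_RINGS.get(aa)
        if ring_names and all(n in atom_by_name for n in ring_names):
            ppts = np.array([atom_by_name[n].coords for n in ring_names])
            pcen, pnorm = _ring_plane(ppts)
            for ring in chem.rings:
                lcen, lnorm = _ring_plane(lig_coords[ring])
                d = np.linalg.norm(pcen - lcen)
                if d > rule.distance_max:
                    continue
                ang = np.degrees(np.arccos(np.clip(abs(np.dot(pnorm, lnorm)), 0, 1)))
                if ang <= PI_PARALLEL_MAX or PI_TSHAPE_MIN <= ang <= PI_TSHAPE_MAX:
                    rec("PI_STACK", ring_names, tuple(ring), d, float(ang))
    return records


def _donor_angle(res, donor, acceptor_pos):
    """Explicit D-H...A angle when a hydrogen rides the donor, else None."""
    hydrogens = [
        a for a in res.atoms
        if a.element == "H" and np.linalg.norm(a.coords - donor.coords) <= 1.25
    ]
    if not hydrogens:
        return None
    return max(_angle(donor.coords, h.coords, acceptor_pos) for h in hydrogens)


def _ligand_donor_angle(ligand, chem, donor_idx, acceptor_pos):
    h_idx = chem.hydrogen_of.get(donor_idx)
    if not h_idx:
        return None
    dpos = ligand.atoms[donor_idx].coords
    return max(_angle(dpos, ligand.atoms[h].coords, acceptor_pos) for h in h_idx)


def _dedupe(records: list[InteractionRecord]) -> list[InteractionRecord]:
    best: dict[tuple[str, int, str], InteractionRecord] = {}
    for r in records:
        key = (r.chain_id, r.residue_number, r.kind)
        if key not in best or r.distance < best[key].distance:
            best[key] = r
    return sorted(
        best.values(), key=lambda r: (r.chain_id, r.residue_number, r.kind, r.distance)
    )


# --- fingerprints --------------------------------------------------------

def fingerprint(records: list[InteractionRecord], site: SiteDefinition) -> FingerprintReport:
    """One row per key residue with the set of contact kinds found there.

    Contacts are pooled over chains (the assembly's three copies of a site
    are equivalent); residues with no contact render as an em-dash.
    """
    by_residue: dict[int, set[str]] = {}
    for r in records:
        by_residue.setdefault(r.residue_number, set()).add(r.kind)
    rows = [
        (f"{code}{number}", frozenset(by_residue.get(number, set())))
        for number, code in site.key_residues
    ]
    return FingerprintReport(site_name=site.name, rows=rows)


def compare_fingerprints(reports: dict[str, FingerprintReport]) -> "pd.DataFrame":
    """Key residues x models table of contact codes, plus a hits summary row."""
    import pandas as pd

    if not reports:
        raise ValueError("no reports to compare")
    items = list(reports.items())
    ref_labels = [label for label, _ in items[0][1].rows]
    for model_id, rep in items[1:]:
        if [label for label, _ in rep.rows] != ref_labels:
            raise ValueError(
                f"report {model_id!r} uses a different site definition"
            )
    data = {model_id: dict(rep.codes()) for model_id, rep in items}
    df = pd.DataFrame(
        {mid: [codes[label] for label in ref_labels] for mid, codes in data.items()},
        index=ref_labels,
    )
    df.loc["n_key_hit"] = [str(rep.n_key_hit) for _, rep in items]
    return df
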