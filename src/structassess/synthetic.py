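"""Synthetic fixtures with planted ground truth.

Everything the assessment pipeline consumes can be generated here without
external downloads: C3-arranged poly-alanine trimers with planted
confidence values, rigidly transformed / noised copies with analytically
known RMSD, ligand pose pairs related by element-preserving permutations,
and binding-site scenes with contacts planted just inside (or just
outside) the detection thresholds.

Every generator returns its output together with a ground-truth record
computed by independent arithmetic (plain loops, exhaustive permutation
search, or an alternative assignment solver) — never by calling the
module the fixture is meant to test. Identical seeds give identical
output.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .model import Atom, Chain, LigandPose, Residue, StructureModel

# --- specs ----------------------------------------------------------------


@dataclass
class ConfidenceProfile:
    """Per-residue confidence plan: base value, site overrides, atom noise."""

    base: float = 80.0
    sitewise: dict[int, float] = field(default_factory=dict)
    atom_noise_sigma: float = 0.0


@dataclass
class Perturbation:
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    angle_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.0


@dataclass
class FixtureSpec:
    seed: int = 0
    n_chains: int = 3
    n_residues: int = 60
    confidence: ConfidenceProfile = field(default_factory=ConfidenceProfile)
    perturbation: Perturbation = field(default_factory=Perturbation)
    ligand_template: str = "atp_like"
    planted_interactions: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ValueError("need at least 10 residues per chain for window tests")


# --- trimer with planted confidence ---------------------------------------

# atoms of a poly-alanine residue with local offsets from the Cα (schematic
# but non-planar, so superpositions are well conditioned)
_RESIDUE_ATOMS = (
    ("N", "N", (-0.53, 1.36, -0.40)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.52, 0.02, 0.20)),
    ("O", "O", (2.20, 1.02, 0.42)),
    ("CB", "C", (-0.54, -0.78, 1.20)),
)
_HELIX_RADIUS = 2.3       # Å
_HELIX_RISE = 1.5         # Å per residue
_HELIX_TWIST = 100.0      # deg per residue
_TRIMER_RADIUS = 15.0     # Å, chain offset from the C3 axis


@dataclass
class TrimerTruth:
    """What the generator wrote: exact per-residue confidence means."""

    residue_means: dict[tuple[str, int], float]

    def windowed_mean(self, chain_id: str, number: int, offsets: tuple[int, ...]) -> float:
        numbers = [number] + [number + o for o in offsets]
        values = [
            self.residue_means[(chain_id, n)]
            for n in numbers
            if (chain_id, n) in self.residue_means
        ]
        return sum(values) / len(values)

    def site_expectation(
        self,
        key_numbers: list[int],
        offsets: tuple[int, ...],
        chain_ids: list[str],
    ) -> tuple[list[float], float]:
        """Chain-averaged windowed means and their global average."""
        per_residue = []
        for number in key_numbers:
            vals = [self.windowed_mean(c, number, offsets) for c in chain_ids]
            per_residue.append(sum(vals) / len(vals))
        return per_residue, sum(per_residue) / len(per_residue)


def _rot_z(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_trimer(spec: FixtureSpec) -> tuple[StructureModel, TrimerTruth]:
    """C3-arranged poly-alanine helical trimer with planted B-values."""
    rng = np.random.default_rng(spec.seed)
    chains = []
    residue_means: dict[tuple[str, int], float] = {}
    for ci in range(spec.n_chains):
        chain_id = chr(ord("A") + ci)
        ring = _rot_z(2.0 * math.pi * ci / max(spec.n_chains, 1))
        residues = []
        for ri in range(1, spec.n_residues + 1):
            phase = math.radians(_HELIX_TWIST) * ri
            ca = np.array(
                [
                    _HELIX_RADIUS * math.cos(phase) + _TRIMER_RADIUS,
                    _HELIX_RADIUS * math.sin(phase),
                    _HELIX_RISE * ri,
                ]
            )
            local = _rot_z(phase)
            planted = spec.confidence.sitewise.get(ri, spec.confidence.base)
            atoms = []
            values = []
            for name, element, offset in _RESIDUE_ATOMS:
                value = planted
                if spec.confidence.atom_noise_sigma > 0:
                    value += rng.normal(0.0, spec.confidence.atom_noise_sigma)
                value = float(np.clip(value, 0.0, 100.0))
                values.append(value)
                coords = ring @ (ca + local @ np.asarray(offset))
                atoms.append(Atom(name=name, element=element, coords=coords, bvalue=round(value, 2)))
            residues.append(Residue(number=ri, aa_code="A", atoms=atoms))
            residue_means[(chain_id, ri)] = sum(a.bvalue for a in atoms) / len(atoms)
        chains.append(Chain(id=chain_id, residues=residues))
    model = StructureModel(
        id=f"synthetic-trimer-seed{spec.seed}",
        chains=chains,
        metadata={"synthetic": True, "seed": spec.seed},
    )
    return model, TrimerTruth(residue_means=residue_means)


# --- transformed copies with known RMSD ------------------------------------


@dataclass
class CopyTruth:
    expected_fixed_rmsd: float     # in the original frame, from stored displacements
    noise_rmsd: float              # RMSD of the drawn noise vectors alone
    rigid_only: bool               # True => Kabsch RMSD is 0 up to numerics


def _axis_angle_matrix(axis, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        return np.eye(3)
    axis = axis / norm
    a = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def make_transformed_copy(
    model: StructureModel, perturbation: Perturbation, seed: int = 0
) -> tuple[StructureModel, CopyTruth]:
    """Rotate + translate + noise a model; the truth holds the exact
    fixed-frame RMSD evaluated from the stored displacement vectors."""
    rng = np.random.default_rng(seed)
    R = _axis_angle_matrix(perturbation.axis, perturbation.angle_deg)
    t = np.asarray(perturbation.translation, dtype=float)
    sq_disp = []
    sq_noise = []
    chains = []
    for chain in model.chains:
        residues = []
        for res in chain.residues:
            atoms = []
            for atom in res.atoms:
                noise = (
                    rng.normal(0.0, perturbation.noise_sigma, size=3)
                    if perturbation.noise_sigma > 0
                    else np.zeros(3)
                )
                new = R @ atom.coords + t + noise
                sq_disp.append(float(np.sum((new - atom.coords) ** 2)))
                sq_noise.append(float(np.sum(noise**2)))
                atoms.append(
                    Atom(
                        name=atom.name, element=atom.element, coords=new,
                        bvalue=atom.bvalue, occupancy=atom.occupancy,
                        is_hetero=atom.is_hetero,
                    )
                )
            residues.append(
                Residue(number=res.number, aa_code=res.aa_code, atoms=atoms,
                        insertion_code=res.insertion_code)
            )
        chains.append(Chain(id=chain.id, residues=residues))
    copy = StructureModel(
        id=f"{model.id}-copy-seed{seed}", chains=chains,
        metadata={**model.metadata, "perturbed_from": model.id},
    )
    truth = CopyTruth(
        expected_fixed_rmsd=math.sqrt(sum(sq_disp) / len(sq_disp)),
        noise_rmsd=math.sqrt(sum(sq_noise) / len(sq_noise)),
        rigid_only=perturbation.noise_sigma == 0,
    )
    return copy, truth


def relabel_chains_cyclically(model: StructureModel, shift: int = 1) -> StructureModel:
    """Rotate chain identities (A->B->C->A for shift 1), keeping coordinates."""
    n = len(model.chains)
    chains = [model.chains[(i + shift) % n] for i in range(n)]
    ids = [c.id for c in model.chains]
    relabeled = [Chain(id=ids[i], residues=chains[i].residues) for i in range(n)]
    return StructureModel(id=f"{model.id}-relabeled", chains=relabeled, metadata=dict(model.metadata))


# --- ligand pose pairs ------------------------------------------------------

#: heavy-atom element multisets of the built-in templates
LIGAND_TEMPLATES = {
    "atp_like": ["C"] * 10 + ["N"] * 5 + ["O"] * 13 + ["P"] * 3,
    "phosphate_like": ["P"] + ["O"] * 4,
}


@dataclass
class PosePairTruth:
    naive_rmsd: float
    sym_rmsd: float
    permutation: list[int]


def _template_pose(template: str | list[str], rng: np.random.Generator, label: str) -> LigandPose:
    if isinstance(template, str):
        elements = LIGAND_TEMPLATES[template]
    else:
        elements = list(template)
    # plausible packing: rejection-sample coordinates with >= 1.2 Å separation
    coords: list[np.ndarray] = []
    while len(coords) < len(elements):
        cand = rng.uniform(-4.0, 4.0, size=3)
        if all(np.linalg.norm(cand - c) >= 1.2 for c in coords):
            coords.append(cand)
    atoms = [
        Atom(name=f"{el}{i + 1}", element=el, coords=c, is_hetero=True)
        for i, (el, c) in enumerate(zip(elements, coords))
    ]
    return LigandPose(label=label, atoms=atoms)


def _element_classes(elements: list[str]) -> dict[str, list[int]]:
    classes: dict[str, list[int]] = {}
    for i, el in enumerate(elements):
        classes.setdefault(el, []).append(i)
    return classes


def oracle_sym_rmsd(
    coordsA: np.ndarray, coordsB: np.ndarray, elements: list[str], exhaustive_max: int = 6
) -> float:
    """Independent symmetry-corrected RMSD oracle.

    Exhaustive search over per-element permutations for classes up to
    ``exhaustive_max`` atoms; larger classes fall back to minimum-weight
    bipartite matching (networkx), a solver independent of the package's
    assignment path.
    """
    total = 0.0
    n = 0
    for element, idx in _element_classes(elements).items():
        A = coordsA[idx]
        B = coordsB[idx]
        k = len(idx)
        n += k
        cost = np.sum((A[:, None, :] - B[None, :, :]) ** 2, axis=2)
        if k <= exhaustive_max:
            best = min(
                sum(cost[i, p[i]] for i in range(k))
                for p in itertools.permutations(range(k))
            )
        else:
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from((("a", i) for i in range(k)), bipartite=0)
            g.add_nodes_from((("b", j) for j in range(k)), bipartite=1)
            for i in range(k):
                for j in range(k):
                    g.add_edge(("a", i), ("b", j), weight=cost[i, j])
            match = nx.algorithms.bipartite.minimum_weight_full_matching(
                g, top_nodes=[("a", i) for i in range(k)]
            )
            best = sum(cost[i, match[("a", i)][1]] for i in range(k))
        total += float(best)
    return math.sqrt(total / n)


def make_pose_pair(
    template: str | list[str] = "atp_like",
    permutation_policy: str = "random_element_preserving",
    displacement: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[LigandPose, LigandPose, PosePairTruth]:
    """Pose B = element-preserving permutation of A, then rigid shift + noise.

    ``swap_equivalents`` exchanges the first two atoms of the largest
    element class; ``random_element_preserving`` shuffles within every
    class; ``identity`` keeps the order.
    """
    rng = np.random.default_rng(seed)
    poseA = _template_pose(template, rng, label="pose-ref")
    elements = poseA.elements()
    classes = _element_classes(elements)

    perm = list(range(len(elements)))
    if permutation_policy == "swap_equivalents":
        largest = max(classes.values(), key=len)
        if len(largest) < 2:
            raise ValueError("swap_equivalents needs an element class of >= 2 atoms")
        perm[largest[0]], perm[largest[1]] = perm[largest[1]], perm[largest[0]]
    elif permutation_policy == "random_element_preserving":
        for idx in classes.values():
            shuffled = list(idx)
            rng.shuffle(shuffled)
            for src, dst in zip(idx, shuffled):
                perm[src] = dst
    elif permutation_policy != "identity":
        raise ValueError(f"unknown permutation policy {permutation_policy!r}")

    t = np.asarray(displacement, dtype=float)
    coordsA = poseA.coords()
    coordsB = coordsA[perm] + t
    if noise_sigma > 0:
        coordsB = coordsB + rng.normal(0.0, noise_sigma, size=coordsB.shape)
    atomsB = [
        Atom(name=f"{elements[perm[i]]}{i + 1}", element=elements[perm[i]],
             coords=coordsB[i], is_hetero=True)
        for i in range(len(elements))
    ]
    poseB = LigandPose(label="pose-moved", atoms=atomsB)
    naive = float(np.sqrt(np.mean(np.sum((coordsB - coordsA) ** 2, axis=1))))
    sym = oracle_sym_rmsd(coordsA, coordsB, elements)
    return poseA, poseB, PosePairTruth(naive_rmsd=naive, sym_rmsd=sym, permutation=perm)


# --- interaction scenes -----------------------------------------------------

# side-chain (plus minimal backbone) templates: the interaction-bearing
# atom sits at the origin and the residue extends along -x, so a ligand
# fragment placed at +x meets only the intended atom
_SCENE_RESIDUES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "K": [  # lysine: NZ is donor and positive center
        ("NZ", "N", (0.0, 0.0, 0.0)), ("CE", "C", (-1.48, 0.2, 0.0)),
        ("CD", "C", (-2.9, -0.3, 0.1)), ("CG", "C", (-4.3, 0.3, 0.0)),
        ("CB", "C", (-5.7, -0.3, 0.1)), ("CA", "C", (-7.1, 0.3, 0.0)),
        ("N", "N", (-7.6, 1.5, 0.6)), ("C", "C", (-8.0, -0.9, -0.4)),
        ("O", "O", (-9.2, -1.0, -0.3)),
    ],
    "R": [  # arginine: CZ is the guanidinium charge center
        ("CZ", "C", (0.0, 0.0, 0.0)), ("NH1", "N", (-0.4, 1.25, 0.0)),
        ("NH2", "N", (-0.4, -1.25, 0.0)), ("NE", "N", (-1.33, 0.0, 0.0)),
        ("CD", "C", (-2.7, 0.5, 0.0)), ("CG", "C", (-4.1, -0.1, 0.1)),
        ("CB", "C", (-5.5, 0.5, 0.0)), ("CA", "C", (-6.9, -0.1, 0.1)),
        ("N", "N", (-7.4, 1.1, 0.7)), ("C", "C", (-7.8, -1.3, -0.3)),
        ("O", "O", (-9.0, -1.4, -0.2)),
    ],
    "N": [  # asparagine: ND2 donor / OD1 acceptor
        ("ND2", "N", (0.0, 0.0, 0.0)), ("CG", "C", (-1.33, 0.2, 0.0)),
        ("OD1", "O", (-1.9, 1.3, 0.0)), ("CB", "C", (-2.2, -1.0, 0.1)),
        ("CA", "C", (-3.6, -0.5, 0.0)), ("N", "N", (-4.1, 0.7, 0.6)),
        ("C", "C", (-4.5, -1.7, -0.4)), ("O", "O", (-5.7, -1.8, -0.3)),
    ],
    "T": [  # threonine: OG1 donor/acceptor
        ("OG1", "O", (0.0, 0.0, 0.0)), ("CB", "C", (-1.4, 0.2, 0.0)),
        ("CG2", "C", (-2.0, -1.2, 0.2)), ("CA", "C", (-2.2, 1.4, -0.1)),
        ("N", "N", (-2.7, 2.0, 1.1)), ("C", "C", (-3.4, 1.2, -1.0)),
        ("O", "O", (-4.6, 1.3, -0.7)),
    ],
    "F": [  # phenylalanine: ring centroid at the origin, ring in the xy-plane
        ("CG", "C", (-1.39, 0.0, 0.0)), ("CD1", "C", (-0.7, 1.2, 0.0)),
        ("CD2", "C", (-0.7, -1.2, 0.0)), ("CE1", "C", (0.7, 1.2, 0.0)),
        ("CE2", "C", (0.7, -1.2, 0.0)), ("CZ", "C", (1.39, 0.0, 0.0)),
        ("CB", "C", (-2.9, 0.0, 0.1)), ("CA", "C", (-3.6, 1.3, 0.0)),
        ("N", "N", (-4.1, 1.9, 1.1)), ("C", "C", (-4.8, 1.1, -0.9)),
        ("O", "O", (-6.0, 1.2, -0.6)),
    ],
    "Y": [  # tyrosine ring (hydroxyl far from the station axis)
        ("CG", "C", (-1.39, 0.0, 0.0)), ("CD1", "C", (-0.7, 1.2, 0.0)),
        ("CD2", "C", (-0.7, -1.2, 0.0)), ("CE1", "C", (0.7, 1.2, 0.0)),
        ("CE2", "C", (0.7, -1.2, 0.0)), ("CZ", "C", (1.39, 0.0, 0.0)),
        ("OH", "O", (2.75, 0.0, 0.0)), ("CB", "C", (-2.9, 0.0, 0.1)),
        ("CA", "C", (-3.6, 1.3, 0.0)), ("N", "N", (-4.1, 1.9, 1.1)),
        ("C", "C", (-4.8, 1.1, -0.9)), ("O", "O", (-6.0, 1.2, -0.6)),
    ],
}

#: ligand fragments per planted kind: atoms relative to the contact atom at
#: the origin, plus intra-fragment bonds
_FRAGMENTS = {
    "SB": (  # phosphate: planted oxygen first, P and far oxygens behind it
        [("O", (0.0, 0.0, 0.0)), ("P", (1.52, 0.0, 0.0)),
         ("O", (2.2, 1.3, 0.0)), ("O", (2.2, -1.3, 0.0)), ("O", (2.2, 0.0, 1.4))],
        [(0, 1), (1, 2), (1, 3), (1, 4)],
    ),
    "HB": (  # lone hydroxyl-like oxygen (acceptor)
        [("O", (0.0, 0.0, 0.0))],
        [],
    ),
    "HI": (  # ethane-like apolar carbon pair
        [("C", (0.0, 0.0, 0.0)), ("C", (1.54, 0.0, 0.0))],
        [(0, 1)],
    ),
    "PI_STACK": (  # benzene ring, centroid at the origin, in-plane like the
        # residue ring so the planted stack is parallel
        [("C", (1.39, 0.0, 0.0)), ("C", (0.7, 1.2, 0.0)), ("C", (-0.7, 1.2, 0.0)),
         ("C", (-1.39, 0.0, 0.0)), ("C", (-0.7, -1.2, 0.0)), ("C", (0.7, -1.2, 0.0))],
        [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)],
    ),
}

# where the interaction-bearing point sits in each residue template, per
# kind (the aromatic centroid is the template origin; Phe's nearest apolar
# carbon is CZ), and the local direction along which the fragment is
# planted: +x toward the assembly center, +z for a parallel ring stack
_CONTACT_POINTS: dict[tuple[str, str], tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    ("K", "SB"): ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
    ("K", "HB"): ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
    ("R", "SB"): ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
    ("N", "HB"): ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
    ("T", "HB"): ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
    ("F", "PI_STACK"): ((0.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
    ("Y", "PI_STACK"): ((0.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
    ("F", "HI"): ((1.39, 0.0, 0.0), (1.0, 0.0, 0.0)),
    ("Y", "HI"): ((0.7, 1.2, 0.0), (1.0, 0.0, 0.0)),
}

# distance from the residue's contact point to the fragment's contact point:
# 0.5 Å inside the rule threshold for positives, 1.0 Å outside for negatives
_PLANT_DISTANCES = {
    "HB": (3.6 - 0.5, 3.6 + 1.0),
    "SB": (5.5 - 0.5, 5.5 + 1.0),
    "HI": (4.0 - 0.5, 4.0 + 1.0),
    "PI_STACK": (5.5 - 0.5, 5.5 + 1.0),
}

#: which residue template carries which planted kind by default
_KIND_RESIDUE = {"SB": "K", "HB": "N", "HI": "F", "PI_STACK": "F"}

_STATION_RADIUS = 25.0


@dataclass
class SceneTruth:
    planted: list[tuple[int, str]]      # positives: (residue number, kind)
    negatives: list[tuple[int, str]]    # placed but out of range


def make_interaction_scene(
    plants: list[tuple[int, str, str]],
    negatives: list[tuple[int, str, str]] | None = None,
    seed: int = 0,
    max_attempts: int = 100,
) -> tuple[StructureModel, LigandPose, SceneTruth]:
    """Build one chain of planted residues and a ligand of matching fragments.

    ``plants``/``negatives`` entries are (residue number, one-letter code,
    kind); the residue template must support the kind (e.g. π-stacking
    needs F or Y). Positives sit 0.5 Å inside the rule threshold,
    negatives 1.0 Å outside. Stations are spread on a circle so planted
    groups never collide; a steric clash (< 1.5 Å between groups)
    triggers regeneration with jitter.
    """
    rng = np.random.default_rng(seed)
    entries = [(num, aa, kind, True) for num, aa, kind in plants] + [
        (num, aa, kind, False) for num, aa, kind in (negatives or [])
    ]
    if not entries:
        return (
            StructureModel(id=f"scene-seed{seed}", chains=[], metadata={"synthetic": True}),
            LigandPose(label="scene-ligand", atoms=[
                Atom(name="C1", element="C", coords=np.array([500.0, 500.0, 500.0]), is_hetero=True)
            ], bonds=None),
            SceneTruth(planted=[], negatives=[]),
        )
    for num, aa, kind, _ in entries:
        if kind not in _FRAGMENTS:
            raise ValueError(f"unknown interaction kind {kind!r}")
        if aa not in _SCENE_RESIDUES:
            raise ValueError(f"no side-chain template for residue type {aa!r}")
        if (aa, kind) not in _CONTACT_POINTS:
            raise ValueError(f"cannot plant a {kind} contact on residue type {aa!r}")

    for attempt in range(max_attempts):
        # per-station jitter moves residue and fragment together, so the
        # planted geometry is preserved while scenes differ across seeds
        jitter = rng.normal(0.0, 0.3, size=(len(entries), 3))
        residues, lig_atoms, lig_bonds = [], [], []
        for k, (num, aa, kind, positive) in enumerate(entries):
            theta = 2.0 * math.pi * k / len(entries)
            radial = np.array([math.cos(theta), math.sin(theta), 0.0])
            tangent = np.array([-math.sin(theta), math.cos(theta), 0.0])
            frame = np.column_stack([-radial, tangent, np.array([0.0, 0.0, 1.0])])
            anchor = _STATION_RADIUS * radial + jitter[k]
            # residue: contact atom at the anchor, body extending outward
            atoms = [
                Atom(name=name, element=el, coords=anchor + frame @ np.asarray(off))
                for name, el, off in _SCENE_RESIDUES[aa]
            ]
            residues.append(Residue(number=num, aa_code=aa, atoms=atoms))
            # fragment: planted at the kind's distance from the residue's
            # contact point, along the kind's local direction
            d = _PLANT_DISTANCES[kind][0 if positive else 1]
            frag_atoms, frag_bonds = _FRAGMENTS[kind]
            contact, direction = _CONTACT_POINTS[(aa, kind)]
            origin = anchor + frame @ (np.asarray(contact) + d * np.asarray(direction))
            base = len(lig_atoms)
            for el, off in frag_atoms:
                lig_atoms.append(
                    Atom(name=f"{el}{len(lig_atoms) + 1}", element=el,
                         coords=origin + frame @ np.asarray(off), is_hetero=True)
                )
            lig_bonds.extend((base + i, base + j) for i, j in frag_bonds)
        if _clash_free(residues, lig_atoms, entries):
            break
    else:
        raise RuntimeError(f"could not build a clash-free scene in {max_attempts} attempts")

    residues.sort(key=lambda r: r.number)
    protein = StructureModel(
        id=f"scene-seed{seed}",
        chains=[Chain(id="A", residues=residues)],
        metadata={"synthetic": True, "seed": seed},
    )
    ligand = LigandPose(label="scene-ligand", atoms=lig_atoms, bonds=lig_bonds or None)
    truth = SceneTruth(
        planted=[(num, kind) for num, _, kind, pos in entries if pos],
        negatives=[(num, kind) for num, _, kind, pos in entries if not pos],
    )
    return protein, ligand, truth


def _clash_free(residues, lig_atoms, entries, min_dist: float = 1.5) -> bool:
    """No two planted groups (different stations) approach below min_dist."""
    groups = []
    n_frag = 0
    for k, res in enumerate(residues):
        frag_len = len(_FRAGMENTS[entries[k][2]][0])
        coords = [a.coords for a in res.atoms]
        coords += [a.coords for a in lig_atoms[n_frag:n_frag + frag_len]]
        n_frag += frag_len
        groups.append(np.array(coords))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            d = np.linalg.norm(groups[i][:, None, :] - groups[j][None, :, :], axis=2)
            if d.min() < min_dist:
                return False
    return True
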