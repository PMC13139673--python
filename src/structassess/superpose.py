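"""Optimal rigid-body superposition (Kabsch) and Cα RMSD between models.

RMSD = sqrt( (1/N) * sum_i |r_i - r_i_ref|^2 ) over N paired atoms.
``rmsd_fixed`` evaluates this in the shared frame; ``kabsch`` first finds
the proper rotation + translation minimizing it (SVD solution with
reflection correction). Model-vs-model comparison pairs Cα atoms on the
intersection of residue numbers per chain position; for homotrimers the
cyclic chain relabelings are searched and the minimal RMSD reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import StructureModel


@dataclass
class CoordinateSet:
    """Ordered point set with (chain, residue number, atom name) labels."""

    points: np.ndarray
    labels: list[tuple[str, int, str]]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points must have equal length")
        if len(self.points) < 1:
            raise ValueError("coordinate set is empty")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # 3x3, proper (det = +1)
    translation: np.ndarray    # applied after rotation
    rmsd: float
    n_paired: int
    unique: bool = True        # False when the point set is degenerate (collinear)

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _model_atoms(model: StructureModel, selection: str):
    """(chain position, residue number, atom name) -> coords, per chain."""
    out = []
    for chain in model.chains:
        entries = {}
        for res in chain.residues:
            for atom in res.atoms:
                if selection == "calpha" and atom.name != "CA":
                    continue
                if selection == "heavy" and atom.element == "H":
                    continue
                entries[(res.number, atom.name)] = (atom.coords, chain.id)
        out.append(entries)
    return out


def pair_calpha(
    modelA: StructureModel,
    modelB: StructureModel,
    chain_map: list[int] | None = None,
    selection: str = "calpha",
) -> tuple[CoordinateSet, CoordinateSet]:
    """Pair atoms on the intersection of (chain position, residue number).

    ``chain_map[i]`` gives the chain position in B paired with chain
    position i of A (identity by default). Chain relabeling searches for
    trimer symmetry are handled by :func:`best_superposition`, which calls
    this with each cyclic map.
    """
    atomsA = _model_atoms(modelA, selection)
    atomsB = _model_atoms(modelB, selection)
    n = min(len(atomsA), len(atomsB))
    if chain_map is None:
        chain_map = list(range(n))
    ptsA, ptsB, labA, labB = [], [], [], []
    for posA, posB in zip(range(n), chain_map):
        common = sorted(set(atomsA[posA]) & set(atomsB[posB]))
        for key in common:
            ca, chA = atomsA[posA][key]
            cb, chB = atomsB[posB][key]
            ptsA.append(ca)
            ptsB.append(cb)
            labA.append((chA, key[0], key[1]))
            labB.append((chB, key[0], key[1]))
    if not ptsA:
        raise ValueError(
            f"no common atoms between {modelA.id} and {modelB.id} "
            f"(selection={selection!r})"
        )
    return (
        CoordinateSet(np.array(ptsA), labA),
        CoordinateSet(np.array(ptsB), labB),
    )


def kabsch(setA: CoordinateSet, setB: CoordinateSet) -> SuperpositionResult:
    """Proper rotation + translation of B minimizing RMSD to A (SVD solution).

    The reflection is corrected by flipping the sign of the smallest
    singular direction when det would be -1, so the result is always a
    rotation. Collinear/degenerate point sets are solved but flagged
    non-unique.
    """
    A = setA.points
    B = setB.points
    if len(A) != len(B):
        raise ValueError(f"length mismatch: {len(A)} vs {len(B)}")
    if len(A) < 1:
        raise ValueError("empty coordinate sets")
    cA = A.mean(axis=0)
    cB = B.mean(axis=0)
    H = (B - cB).T @ (A - cA)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cA - R @ cB
    diffs = (B @ R.T + t) - A
    rmsd = float(np.sqrt(np.mean(np.sum(diffs**2, axis=1))))
    # rotation is non-unique when the centered points span < 2 dimensions
    unique = len(A) >= 3 and S[1] > 1e-8 * max(S[0], 1.0)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_paired=len(A), unique=unique)


def rmsd_fixed(setA: CoordinateSet, setB: CoordinateSet) -> float:
    """RMSD of paired distances in the shared frame — no fitting."""
    A = setA.points
    B = setB.points
    if len(A) != len(B):
        raise ValueError(f"length mismatch: {len(A)} vs {len(B)}")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def _cyclic_maps(n: int) -> list[list[int]]:
    return [[(i + s) % n for i in range(n)] for s in range(n)]


def best_superposition(
    modelA: StructureModel,
    modelB: StructureModel,
    trimer_symmetry: bool = True,
    all_permutations: bool = False,
    selection: str = "calpha",
) -> SuperpositionResult:
    """Kabsch superposition, searching chain relabelings when symmetric.

    With ``trimer_symmetry`` and equal chain counts the cyclic chain
    permutations (the C3 relabelings) are tried and the minimal-RMSD one
    returned; ``all_permutations`` widens the search to every relabeling.
    """
    nA, nB = len(modelA.chains), len(modelB.chains)
    if trimer_symmetry and nA == nB and nA > 1:
        if all_permutations:
            maps = [list(p) for p in itertools.permutations(range(nA))]
        else:
            maps = _cyclic_maps(nA)
    else:
        maps = [None]
    best: SuperpositionResult | None = None
    for cmap in maps:
        try:
            sA, sB = pair_calpha(modelA, modelB, chain_map=cmap, selection=selection)
        except ValueError:
            continue
        result = kabsch(sA, sB)
        if best is None or result.rmsd < best.rmsd:
            best = result
    if best is None:
        raise ValueError(f"no valid pairing between {modelA.id} and {modelB.id}")
    return best


def rmsd_matrix(
    models: list[StructureModel],
    trimer_symmetry: bool = True,
    selection: str = "calpha",
) -> "pd.DataFrame":
    """All-pairs Kabsch RMSD matrix (Å); diagonal 0, missing pairs NaN."""
    import pandas as pd

    if len(models) < 2:
        raise ValueError("need at least two models")
    ids = [m.id for m in models]
    mat = np.zeros((len(models), len(models)))
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            try:
                r = best_superposition(
                    models[i], models[j], trimer_symmetry=trimer_symmetry, selection=selection
                ).rmsd
            except ValueError:
                r = np.nan
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=ids, columns=ids)


def rmsd_matrix_tsv(matrix: "pd.DataFrame", path, ndigits: int = 3) -> None:
    """Write the matrix as TSV, rounded to table precision (3 decimals)."""
    matrix.round(ndigits).to_csv(path, sep="\t", float_format=f"%.{ndigits}f", na_rep="NA")
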