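"""Ligand-pose metrics for docking validation.

Docked and crystallographic poses share the receptor frame, so pose RMSD
is computed without fitting. Chemically equivalent atoms (e.g. the three
terminal phosphate oxygens of ATP) can be indexed differently by a docking
engine than by the crystal record, inflating the naive RMSD; the
symmetry-corrected RMSD removes this by finding, per chemical element, the
one-to-one atom correspondence minimizing the total sum of squared
distances (linear assignment / Hungarian method) and pooling all pairs.

A redocking is conventionally judged satisfactory when the pose RMSD is
strictly below 2.0 Å. Docking grids are boxes centered on the geometric
center of a reference ligand, 40 x 30 x 40 Å by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .model import LigandPose

REDOCK_THRESHOLD: float = 2.0       # Å, strict "below"
DEFAULT_GRID_DIMS = (40.0, 30.0, 40.0)  # Å


@dataclass
class AtomAssignment:
    """Optimal per-element atom correspondence between two poses."""

    pairs: list[tuple[int, int]]
    per_element: dict[str, list[int]]   # element -> indices into ``pairs``
    total_cost: float                   # sum of squared distances, Å²


@dataclass
class SymRmsdResult:
    sym_rmsd: float
    naive_rmsd: float | None
    assignment: AtomAssignment
    threshold: float = REDOCK_THRESHOLD

    @property
    def passes_redock(self) -> bool:
        return self.sym_rmsd < self.threshold


@dataclass
class GridBox:
    center: np.ndarray
    dims: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_GRID_DIMS))

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.dims = np.asarray(self.dims, dtype=float)
        if self.dims.shape != (3,) or np.any(self.dims <= 0):
            raise ValueError("grid dimensions must be three strictly positive lengths")

    def as_dict(self) -> dict:
        return {"center": self.center.tolist(), "dims": self.dims.tolist()}


def naive_rmsd(poseA: LigandPose, poseB: LigandPose, heavy_only: bool = True) -> float:
    """Pose RMSD under the identity atom mapping, no fitting."""
    elemA = poseA.elements(heavy_only)
    elemB = poseB.elements(heavy_only)
    if elemA != elemB:
        raise ValueError(
            "ordered element sequences differ between poses; use symmetry_rmsd, "
            "which matches atoms within each element"
        )
    A = poseA.coords(heavy_only)
    B = poseB.coords(heavy_only)
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def solve_assignment(cost: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Optimal assignment on a square non-negative cost matrix.

    Ties are broken deterministically: among the optimal assignments the
    lexicographically smallest pair list is returned (rows in order, each
    matched to the smallest feasible column).
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError(f"cost matrix must be square, got {cost.shape}")
    if np.any(cost < 0):
        raise ValueError("cost matrix entries must be non-negative")
    n = cost.shape[0]
    rows, cols = linear_sum_assignment(cost)
    optimum = float(cost[rows, cols].sum())
    # lexicographic refinement: fix rows in order to the smallest column
    # that still allows an optimal completion
    tol = 1e-9 * max(1.0, abs(optimum))
    free_cols = list(range(n))
    pairs: list[tuple[int, int]] = []
    fixed = 0.0
    for i in range(n):
        for k, j in enumerate(list(free_cols)):
            remaining_rows = list(range(i + 1, n))
            rest_cols = [c for c in free_cols if c != j]
            if remaining_rows:
                sub = cost[np.ix_(remaining_rows, rest_cols)]
                r, c = linear_sum_assignment(sub)
                rest = float(sub[r, c].sum())
            else:
                rest = 0.0
            if fixed + cost[i, j] + rest <= optimum + tol:
                pairs.append((i, j))
                fixed += float(cost[i, j])
                free_cols.remove(j)
                break
        else:  # pragma: no cover - optimal completion always exists
            raise RuntimeError("assignment refinement failed")
    return pairs, optimum


def symmetry_rmsd(
    poseA: LigandPose,
    poseB: LigandPose,
    heavy_only: bool = True,
    threshold: float = REDOCK_THRESHOLD,
) -> SymRmsdResult:
    """Symmetry-corrected pose RMSD via per-element optimal assignment.

    For each element the |A_e| x |B_e| matrix of squared distances is
    built and the assignment minimizing its total solved; all assigned
    pairs are pooled and sym_rmsd = sqrt(total_cost / N). No fitting is
    applied — the poses are compared in the receptor frame.
    """
    atomsA = poseA.heavy_atoms() if heavy_only else poseA.atoms
    atomsB = poseB.heavy_atoms() if heavy_only else poseB.atoms
    byA: dict[str, list[int]] = {}
    byB: dict[str, list[int]] = {}
    for i, a in enumerate(atomsA):
        byA.setdefault(a.element, []).append(i)
    for j, b in enumerate(atomsB):
        byB.setdefault(b.element, []).append(j)
    mismatched = {
        e for e in set(byA) | set(byB)
        if len(byA.get(e, [])) != len(byB.get(e, []))
    }
    if mismatched:
        raise ValueError(
            f"element multisets differ between poses for: {sorted(mismatched)}"
        )
    pairs: list[tuple[int, int]] = []
    per_element: dict[str, list[int]] = {}
    total_cost = 0.0
    for element in sorted(byA):
        ia = byA[element]
        jb = byB[element]
        coordsA = np.array([atomsA[i].coords for i in ia])
        coordsB = np.array([atomsB[j].coords for j in jb])
        cost = cdist(coordsA, coordsB, metric="sqeuclidean")
        local_pairs, cost_e = solve_assignment(cost)
        idx0 = len(pairs)
        pairs.extend((ia[i], jb[j]) for i, j in local_pairs)
        per_element[element] = list(range(idx0, len(pairs)))
        total_cost += cost_e
    n = len(pairs)
    if n == 0:
        raise ValueError("no atoms left to compare after filtering")
    sym = float(np.sqrt(total_cost / n))
    try:
        naive = naive_rmsd(poseA, poseB, heavy_only)
    except ValueError:
        naive = None
    assignment = AtomAssignment(pairs=pairs, per_element=per_element, total_cost=total_cost)
    return SymRmsdResult(sym_rmsd=sym, naive_rmsd=naive, assignment=assignment, threshold=threshold)


def classify_redock(result: SymRmsdResult) -> str:
    """'satisfactory' iff sym_rmsd is strictly below the threshold."""
    return "satisfactory" if result.sym_rmsd < result.threshold else "unsatisfactory"


def grid_from_ligand(
    pose: LigandPose,
    dims: tuple[float, float, float] = DEFAULT_GRID_DIMS,
    heavy_only: bool = True,
) -> GridBox:
    """Docking grid box centered on the ligand's geometric center."""
    coords = pose.coords(heavy_only)
    if len(coords) == 0:
        raise ValueError(f"pose {pose.label}: no atoms to center a grid on")
    return GridBox(center=coords.mean(axis=0), dims=np.asarray(dims, dtype=float))
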