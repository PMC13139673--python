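import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structassess import (
    classify_redock,
    grid_from_ligand,
    naive_rmsd,
    solve_assignment,
    symmetry_rmsd,
)
from structassess import synthetic as syn
from structassess.ligand import AtomAssignment, SymRmsdResult
from structassess.model import Atom, LigandPose


def _pose(entries, label="pose"):
    atoms = [
        Atom(name=f"{el}{i + 1}", element=el, coords=np.asarray(xyz, dtype=float), is_hetero=True)
        for i, (el, xyz) in enumerate(entries)
    ]
    return LigandPose(label=label, atoms=atoms)


# ---- naive RMSD ----------------------------------------------------------

def test_naive_rmsd_identical_poses_is_zero():
    pose = _pose([("C", (0, 0, 0)), ("O", (1, 1, 1))])
    assert naive_rmsd(pose, pose) == 0.0


def test_naive_rmsd_single_displaced_atom():
    a = _pose([("C", (0, 0, 0)), ("O", (1, 0, 0))])
    b = _pose([("C", (0, 0, 0)), ("O", (1, 0, 1))])
    assert naive_rmsd(a, b) == pytest.approx(np.sqrt(0.5), abs=1e-12)


def test_naive_rmsd_element_sequence_mismatch():
    a = _pose([("C", (0, 0, 0)), ("O", (1, 0, 0))])
    b = _pose([("O", (0, 0, 0)), ("C", (1, 0, 0))])
    with pytest.raises(ValueError, match="symmetry_rmsd"):
        naive_rmsd(a, b)


def test_naive_rmsd_matches_generator_truth():
    _, _, truth = syn.make_pose_pair(
        "atp_like", "identity", displacement=(0.3, -0.2, 0.1), noise_sigma=0.4, seed=21
    )
    poseA, poseB, truth2 = syn.make_pose_pair(
        "atp_like", "identity", displacement=(0.3, -0.2, 0.1), noise_sigma=0.4, seed=21
    )
    assert naive_rmsd(poseA, poseB) == pytest.approx(truth2.naive_rmsd, abs=1e-9)
    assert truth.naive_rmsd == truth2.naive_rmsd  # generator determinism


# ---- assignment solver ---------------------------------------------------

def test_assignment_two_by_two():
    pairs, cost = solve_assignment(np.array([[1.0, 2.0], [3.0, 1.0]]))
    assert pairs == [(0, 0), (1, 1)]
    assert cost == pytest.approx(2.0)


def test_assignment_zero_diagonal():
    n = 4
    cost = np.ones((n, n)) - np.eye(n)
    pairs, total = solve_assignment(cost)
    assert pairs == [(i, i) for i in range(n)]
    assert total == pytest.approx(0.0)


def test_assignment_tie_breaks_lexicographically():
    # every assignment costs the same; the refined answer must be the
    # identity (lexicographically smallest pair list)
    pairs, _ = solve_assignment(np.ones((3, 3)))
    assert pairs == [(0, 0), (1, 1), (2, 2)]


@pytest.mark.parametrize("seed", range(25))
def test_assignment_matches_exhaustive_minimum(seed):
    rng = np.random.default_rng(seed)
    cost = rng.uniform(0, 10, size=(6, 6))
    pairs, total = solve_assignment(cost)
    brute = min(
        sum(cost[i, p[i]] for i in range(6)) for p in itertools.permutations(range(6))
    )
    assert total == pytest.approx(brute, abs=1e-9)
    assert sorted(i for i, _ in pairs) == list(range(6))
    assert sorted(j for _, j in pairs) == list(range(6))


def test_assignment_rejects_bad_input():
    with pytest.raises(ValueError, match="square"):
        solve_assignment(np.ones((2, 3)))
    with pytest.raises(ValueError, match="non-negative"):
        solve_assignment(np.array([[1.0, -0.1], [0.2, 0.3]]))


# ---- symmetry-corrected RMSD ---------------------------------------------

def test_swapped_equivalent_atoms_cost_nothing():
    """Two equivalent oxygens swapped in index: naive RMSD is inflated to
    2r, the symmetry-corrected RMSD sees the identical geometry."""
    a = _pose([("O", (1, 0, 0)), ("O", (-1, 0, 0))])
    b = _pose([("O", (-1, 0, 0)), ("O", (1, 0, 0))])
    result = symmetry_rmsd(a, b)
    assert result.naive_rmsd == pytest.approx(2.0)
    assert result.sym_rmsd == pytest.approx(0.0, abs=1e-12)


def test_identical_poses_pass_redock():
    pose, _, _ = syn.make_pose_pair("atp_like", "identity", seed=1)
    result = symmetry_rmsd(pose, pose)
    assert result.sym_rmsd == 0.0
    assert result.passes_redock
    assert classify_redock(result) == "satisfactory"


def test_element_multiset_mismatch_lists_elements():
    a = _pose([("C", (0, 0, 0)), ("O", (1, 0, 0))])
    b = _pose([("C", (0, 0, 0)), ("N", (1, 0, 0))])
    with pytest.raises(ValueError) as err:
        symmetry_rmsd(a, b)
    assert "N" in str(err.value) and "O" in str(err.value)


@pytest.mark.parametrize("seed", range(20))
def test_sym_rmsd_equals_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    elements = ["C"] * int(rng.integers(2, 6)) + ["O"] * int(rng.integers(2, 6)) + ["N"]
    poseA, poseB, truth = syn.make_pose_pair(
        elements, "random_element_preserving",
        displacement=tuple(rng.normal(0, 1, 3)), noise_sigma=0.5, seed=seed,
    )
    result = symmetry_rmsd(poseA, poseB)
    assert result.sym_rmsd == pytest.approx(truth.sym_rmsd, abs=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_sym_rmsd_properties(seed):
    rng = np.random.default_rng(1000 + seed)
    poseA, poseB, _ = syn.make_pose_pair(
        "atp_like", "random_element_preserving",
        displacement=tuple(rng.normal(0, 2, 3)), noise_sigma=1.0, seed=seed,
    )
    fwd = symmetry_rmsd(poseA, poseB)
    # never above the naive identity mapping
    assert fwd.sym_rmsd <= fwd.naive_rmsd + 1e-12
    # symmetric in its arguments
    assert fwd.sym_rmsd == pytest.approx(symmetry_rmsd(poseB, poseA).sym_rmsd, abs=1e-9)
    # permutation of one pose costs nothing
    permA, _, _ = syn.make_pose_pair("atp_like", "identity", seed=seed)
    perm = list(np.random.default_rng(seed).permutation(len(permA.atoms)))
    by_el: dict[str, list[int]] = {}
    for i, a in enumerate(permA.atoms):
        by_el.setdefault(a.element, []).append(i)
    # element-preserving shuffle
    perm = list(range(len(permA.atoms)))
    for idx in by_el.values():
        shuffled = list(np.array(idx)[np.random.default_rng(seed).permutation(len(idx))])
        for src, dst in zip(idx, shuffled):
            perm[src] = dst
    permuted = LigandPose(label="perm", atoms=[permA.atoms[i] for i in perm])
    assert symmetry_rmsd(permA, permuted).sym_rmsd == pytest.approx(0.0, abs=1e-12)


def test_rigid_translation_bounded_by_shift_length(rng):
    poseA, poseB, _ = syn.make_pose_pair(
        "atp_like", "random_element_preserving", noise_sigma=0.8, seed=5
    )
    base = symmetry_rmsd(poseA, poseB).sym_rmsd
    t = rng.normal(size=3)
    shifted = LigandPose(
        label="shifted",
        atoms=[
            Atom(name=a.name, element=a.element, coords=a.coords + t, is_hetero=True)
            for a in poseB.atoms
        ],
    )
    assert symmetry_rmsd(poseA, shifted).sym_rmsd <= base + np.linalg.norm(t) + 1e-9


def test_hydrogens_excluded_by_default():
    a = _pose([("C", (0, 0, 0)), ("H", (1, 0, 0))])
    b = _pose([("C", (0, 0, 0)), ("H", (9, 9, 9))])
    assert symmetry_rmsd(a, b).sym_rmsd == pytest.approx(0.0)
    assert symmetry_rmsd(a, b, heavy_only=False).sym_rmsd > 1.0


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    n_c=st.integers(1, 4),
    n_o=st.integers(1, 4),
    seed=st.integers(0, 2**16),
)
def test_sym_rmsd_bounded_by_naive_property(n_c, n_o, seed):
    """For any pose pair with matching element sequences, correcting the
    atom correspondence can only lower the RMSD."""
    rng = np.random.default_rng(seed)
    elements = ["C"] * n_c + ["O"] * n_o
    a = _pose([(e, rng.uniform(-5, 5, 3)) for e in elements])
    b = _pose([(e, rng.uniform(-5, 5, 3)) for e in elements])
    result = symmetry_rmsd(a, b)
    assert result.sym_rmsd <= naive_rmsd(a, b) + 1e-12
    assert result.sym_rmsd >= 0.0


# ---- redocking criterion -------------------------------------------------

@pytest.mark.parametrize(
    "value,expected",
    [
        (0.5, "satisfactory"),
        (1.9999999, "satisfactory"),
        (2.0, "unsatisfactory"),     # strict "below 2.0 Å"
        (2.0000001, "unsatisfactory"),
        (3.7, "unsatisfactory"),
    ],
)
def test_redock_threshold_is_strict(value, expected):
    result = SymRmsdResult(
        sym_rmsd=value, naive_rmsd=value,
        assignment=AtomAssignment(pairs=[(0, 0)], per_element={"C": [0]}, total_cost=value**2),
    )
    assert classify_redock(result) == expected
    assert result.passes_redock == (expected == "satisfactory")


# ---- grid box ------------------------------------------------------------

def test_grid_center_is_geometric_center():
    pose = _pose([("C", (0, 0, 0)), ("C", (2, 0, 0)), ("C", (1, 3, 0))])
    box = grid_from_ligand(pose)
    np.testing.assert_allclose(box.center, [1.0, 1.0, 0.0])
    np.testing.assert_allclose(box.dims, [40.0, 30.0, 40.0])  # default grid


def test_grid_single_atom_and_hydrogen_filtering():
    pose = _pose([("P", (5, -1, 2))])
    np.testing.assert_allclose(grid_from_ligand(pose).center, [5, -1, 2])
    with_h = _pose([("P", (5, -1, 2)), ("H", (100, 0, 0))])
    np.testing.assert_allclose(grid_from_ligand(with_h).center, [5, -1, 2])


def test_grid_rejects_empty_selection_and_bad_dims():
    only_h = _pose([("H", (0, 0, 0))])
    with pytest.raises(ValueError, match="no atoms"):
        grid_from_ligand(only_h)
    pose = _pose([("C", (0, 0, 0))])
    with pytest.raises(ValueError, match="positive"):
        grid_from_ligand(pose, dims=(40.0, 0.0, 40.0))
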