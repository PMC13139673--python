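"""Symmetry-corrected RMSD for redocking validation.

Builds an ATP-like pose (31 heavy atoms) and a copy whose
symmetry-equivalent atoms are re-indexed and whose coordinates are
shifted 0.8 Å. The naive RMSD is inflated by the index permutation; the
symmetry-corrected RMSD matches atoms of the same element optimally
(Hungarian assignment) and recovers the true 0.8 Å deviation, which
passes the conventional < 2.0 Å redocking criterion. Also prints the
docking grid box centered on the reference pose.
"""

from structassess import classify_redock, grid_from_ligand, symmetry_rmsd
from structassess import synthetic as syn

reference, docked, truth = syn.make_pose_pair(
    "atp_like",
    permutation_policy="random_element_preserving",
    displacement=(0.8, 0.0, 0.0),
    seed=42,
)

result = symmetry_rmsd(reference, docked)
print(f"naive RMSD (identity mapping):      {result.naive_rmsd:.3f} Å")
print(f"symmetry-corrected RMSD:            {result.sym_rmsd:.3f} Å")
print(f"oracle (exhaustive/matching) value: {truth.sym_rmsd:.3f} Å")
print(f"redocking at 2.0 Å threshold:       {classify_redock(result)}")

box = grid_from_ligand(reference)
center = ", ".join(f"{c:.2f}" for c in box.center)
dims = " x ".join(f"{d:g}" for d in box.dims)
print(f"\ndocking grid box: center ({center}) Å, dims {dims} Å")
print(
    "\nThe index permutation alone inflates the naive RMSD several-fold; "
    "per-element optimal assignment removes exactly that artifact."
)
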