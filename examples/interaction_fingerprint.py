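"""Geometric protein-ligand contacts and a key-residue fingerprint.

Builds a binding-site scene with contacts planted just inside the
detection thresholds — salt bridges at four lysines/arginine, hydrogen
bonds at two residues, nothing at T189 — mirroring the contact pattern a
docking study reports for an ATP pose, then detects the contacts
geometrically and renders the per-residue code table
(HB = hydrogen bond, SB = salt bridge, — = no contact).
"""

from structassess import SiteDefinition, detect_interactions, fingerprint
from structassess import synthetic as syn

plants = [
    (64, "K", "SB"), (66, "K", "SB"), (145, "K", "HB"),
    (292, "N", "HB"), (294, "R", "SB"), (311, "K", "SB"),
]
protein, ligand, truth = syn.make_interaction_scene(
    plants, negatives=[(189, "T", "HB")], seed=7
)

records = detect_interactions(protein, ligand)
print("detected contacts:")
for r in records:
    print(f"  {r.residue_label:>6}  {r.kind:<8} {r.distance:.2f} Å")

site = SiteDefinition(
    "orthosteric",
    [(64, "K"), (66, "K"), (145, "K"), (189, "T"), (292, "N"), (294, "R"), (311, "K")],
)
fp = fingerprint(records, site)
print("\nKey residue\tInteraction")
for label, code in fp.codes():
    print(f"{label}\t{code}")
print(f"\nkey residues contacted: {fp.n_key_hit} of {len(fp.rows)}")
print("Every planted contact is recovered; the out-of-range placement at T189 stays '—'.")
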