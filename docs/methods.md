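# Methods

This note documents the models and procedures implemented in
`structassess`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the numerical conventions.

## Structure model and confidence convention

Structures are parsed (gemmi) into a plain chain → residue → atom
hierarchy keyed by author residue numbering, which is assumed consistent
across models built from the same full-length sequence; no renumbering or
sequence alignment is attempted. The B-factor channel of a predicted
model is interpreted as pLDDT (0–100), the convention used by
structure-prediction servers when depositing models. A model flagged
`experimental` in its metadata keeps crystallographic B-factors and is
excluded from confidence operations. Model-level scores (pTM, ipTM) are
carried as metadata only, never computed.

Parsing rules: all ATOM/HETATM records are kept, hydrogens included
(downstream operations decide whether to use them); for alternate
locations only the highest-occupancy conformer is retained, ties broken
toward altloc `A`; elements missing from the file are inferred from atom
names; insertion codes are supported but warn, since predicted models
should not carry them. PDB coordinates outside the fixed-width `%8.3f`
field range are a write error rather than silent truncation.

## Site confidence

AlphaFold 2 deposits one pLDDT per residue (every atom repeats it);
AlphaFold 3 deposits per-atom values. Both are unified by one code path:
the residue value is the unweighted mean of its atoms' B-values
(`atom_mean`), which is exact for the residue-level convention. A
`ca_only` mode exists for users who prefer the Cα convention.

A site is a named, ordered list of key residues with their expected
one-letter codes; the expectation is checked at lookup and a mismatch is
a hard error, because it almost always means numbering drift between
models rather than a biological difference. Built-in definitions cover
the P2X7 receptor's ATP (orthosteric: K64, K66, T189, N292, R294, K311)
and antagonist (allosteric: F88, F95, F103, M105, F293, V312) pockets;
position 312 is valine in the canonical sequence, and an alanine variant
of that site can be configured where a study reports A312.

Each key residue's value is averaged over a sequence window — the residue
plus `neighbor_offsets`, default `(-3, -2, -1, +1, +2)`. "Five adjacent
residues" is directionally ambiguous; the default takes the five nearest
sequence neighbors with the tie toward the N-terminus, and the offsets
are fully configurable (including empty, which reduces the windowed value
to the bare residue mean) so any published convention can be matched.
Windows are clipped at chain termini without error; the effective window
size is reported. Per-residue values are averaged across all chains that
contain the residue (`average_all`, the natural choice for a homotrimer
reported as one value per residue), or taken from a single chain. The
site global average is the arithmetic mean of the key residues' values.
Reporting rounds to 2 decimals; internal computation is full precision.

## Superposition and model comparison

Atoms are paired on the intersection of (chain position, residue number,
atom name), Cα-only by default — model comparison figures in this field
conventionally quote Cα RMSD — with heavy-atom and all-atom selections
behind a flag. Pairing by number intersection handles models that lack
template-absent regions without alignment. For equal chain counts the
cyclic chain relabelings (the C3 symmetry of a trimer) are searched and
the minimal-RMSD labeling reported; the full factorial search is
available but off by default.

The Kabsch rotation is computed from the SVD of the cross-covariance of
the centered point sets; the sign of the smallest singular direction is
flipped when the determinant would be −1, so the result is always a
proper rotation (reflections are never allowed to fake similarity).
Degenerate inputs (fewer than 3 points, or collinear sets whose second
singular value vanishes) are solved but flagged non-unique. The
implementation is cross-checked in the test suite against an independent
SVD-based superposition (scipy's rotation alignment) and against a
random-transform search oracle that, by construction, can approach but
never beat the closed-form optimum.

The all-pairs matrix reports Kabsch RMSD with a zero diagonal, symmetric
within 1e-9, rounded to 3 decimals in TSV output; a failed pairing is a
missing entry, never a silent zero.

## Ligand-pose metrics

Pose RMSD is computed without superposition: a docked pose and the
crystallographic reference live in the same receptor frame, and fitting
would hide placement error. An optional receptor-frame pre-alignment (via
the superposition module) exists for cross-model comparisons.

Hydrogens are excluded by default (`heavy_only`): docking outputs and
crystal references rarely agree on hydrogen placement, and including them
would mix protonation conventions into a geometry metric. A flag restores
them.

The symmetry-corrected RMSD builds, for each chemical element, the
squared-distance cost matrix between the element's atoms in the two poses
and solves the linear assignment exactly
(`scipy.optimize.linear_sum_assignment`); all assigned pairs are pooled
and the RMSD taken over the union. Assignment is per-element only, not
constrained by the molecular graph — this can pair chemically
non-equivalent atoms of the same element, which is accepted as the
definition of the metric; a graph-automorphism-aware mode is a non-goal.
Ties between optimal assignments are broken deterministically to the
lexicographically smallest pair list (rows in order, each fixed to the
smallest column that still permits an optimal completion).

The redocking criterion is strict: satisfactory ⇔ sym-RMSD < 2.0 Å.
Equality at the threshold is unsatisfactory. Grid boxes default to
40 × 30 × 40 Å centered on the unweighted heavy-atom centroid of the
reference ligand.

## Interaction detection

Contact geometry is computed directly rather than delegated to an
external profiler, so runs are reproducible and thresholds are explicit
and configurable:

| kind | criterion | default |
| --- | --- | --- |
| HB | donor–acceptor heavy-atom distance | ≤ 3.6 Å, D–H…A ≥ 100° when H present |
| SB | distance between opposite charged centers | ≤ 5.5 Å |
| HI | apolar carbon–carbon distance | ≤ 4.0 Å |
| π-s | ring centroid distance + interplanar angle | ≤ 5.5 Å; ≤ 30° or 60–90° |

These follow the published geometric criteria of the widely used
interaction-profiler family; exact thresholds vary between profiler
versions, which is why they are exposed in config rather than hard-coded
as truth. Protein donors/acceptors, charge centers (Lys NZ, Arg
guanidinium CZ, His ring N; Asp/Glu carboxylate O) and apolar carbons
come from per-residue lookup tables over standard atom names. Ligand
atom classes are perceived from element plus bond topology — bonds from
the SDF block when present, otherwise inferred by covalent radii
(≤ 1.25 × Σ radii). Phosphate and carboxylate oxygens are negative,
four-coordinate nitrogens positive; an explicit charge annotation
overrides inference. Rings are 5–6-membered C/N cycles of the bond
graph's cycle basis, accepted as aromatic when planar within 0.15 Å.
Without explicit hydrogens, hydrogen bonds fall back to the heavy-atom
distance criterion alone. Duplicate contacts collapse to the shortest
per (residue, kind); output ordering is deterministic.

Fingerprints tabulate, per key residue of a site, the set of contact
kinds found anywhere in the assembly (the three copies of a homotrimer's
site are equivalent), rendered with the conventional codes and an em-dash
for none. Water-mediated contacts, halogen bonds, π-cation and metal
coordination are out of scope.

## Synthetic data: what it emulates, what it does not

The generator exists to give every consumer a fixture with independently
computed ground truth:

* **Trimers** are C3-arranged poly-alanine helices (5 atoms/residue,
  schematic ideal-helix geometry). Only numbering, confidence and
  rigid-geometry semantics matter; the backbone is not claimed to be
  stereochemically valid. Confidence profiles plant a base value, per-residue
  overrides and optional per-atom Gaussian noise; the truth records the
  exact per-residue means as written and recomputes windowed site
  expectations with plain dictionary arithmetic, independent of the
  confidence module.
* **Transformed copies** apply an axis–angle rotation, translation and
  optional per-atom noise; the truth evaluates the fixed-frame RMSD
  directly from the stored displacement vectors. Pure rigid motions have
  Kabsch RMSD 0 by construction.
* **Pose pairs** permute atoms within element classes, then shift and
  noise. The ground-truth corrected RMSD comes from an exhaustive
  per-element permutation search for classes up to 6 atoms and from
  minimum-weight bipartite matching (networkx) for larger classes — a
  solver independent of the package's assignment path, so the dual-route
  check is preserved for the 13-oxygen ATP-like template (10 C, 5 N,
  13 O, 3 P heavy atoms; an element-multiset stand-in, not a valid
  molecule).
* **Interaction scenes** place real side-chain templates (Lys, Arg, Asn,
  Thr, Phe, Tyr) on a 25 Å circle with matched ligand fragments
  (phosphate, hydroxyl oxygen, ethane, benzene) planted 0.5 Å inside the
  detection threshold for positives and 1.0 Å outside for negatives,
  measured at the interaction-bearing atoms. Station jitter moves each
  residue–fragment pair rigidly, so scenes vary across seeds without
  disturbing the planted geometry; a steric clash between stations
  triggers regeneration, with an error after 100 attempts.

Because the fixtures are schematic, passing tests demonstrate the
correctness of the *computations* — extraction, aggregation,
superposition, assignment, geometric classification — not the behavior of
the thresholds on real binding sites. Real structures carry alternate
conformations, missing residues, non-ideal protonation and profiler
version differences that the generator deliberately does not model, and
interaction results on real complexes may legitimately differ from any
particular external profiler's output.

All generators draw from a single explicitly seeded RNG stream per call;
identical spec and seed give byte-identical files.

## Assessment runs

The pipeline stage runs the four analyses from one TOML config and writes
TSV/JSON per table plus a Markdown summary and a provenance block (config
hash, seed, input digests). Stages are isolated: a failure is recorded
and the remaining stages still run; the process exit status reflects
stage failures, while failing the 2.0 Å criterion is data, not an error.
Outputs contain no timestamps, so re-running a config reproduces the
report byte for byte.

## Problem sizes and tolerances

Validation batteries use 50-point clouds with 100 rigid motions and
10,000 random-transform trials (Kabsch), 50 oracle pose pairs with ≤ 6
atoms per element plus 1,000 random pairs for the sym ≤ naive bound, and
100 seeded scenes/profiles for planted-truth recovery — sizes at which
the exhaustive oracles are exact and the full suite runs in seconds.
Numerical assertions use 1e-9 for identities that hold to machine
precision, 1e-12 for exact bounds, and the table precisions (2 decimals
for confidence, 3 for RMSD) for reported values.

## Known limitations

* Chain correspondence in superposition assumes equal chain counts and,
  by default, cyclic relabelings only.
* Per-element assignment can match chemically inequivalent atoms; for
  molecules where this matters, compare with a graph-aware tool.
* Interaction detection without hydrogens cannot evaluate donor angles
  and therefore over-accepts borderline hydrogen bonds relative to a
  protonated run.
* Ligand charge perception is rule-based (phosphate/carboxylate O⁻,
  quaternary N⁺); unusual functional groups need the explicit charge
  annotation.
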