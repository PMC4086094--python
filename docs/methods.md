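# Methods

## Problem and model

Mutating a buried hydrophobic residue removes packing interactions in
the protein core and lowers thermal stability; at a suitable position
the destabilized protein folds and functions at low (permissive)
temperature but not above a restrictive temperature. The package
predicts such positions from either the primary sequence or a 3D
structure, and suggests five stereochemically diverse substitutions
(Ala, Trp, Asn, Asp, Pro; the wild type is excluded, no ranking) so that
at least one is likely to yield a Ts phenotype. Only Val, Ile, Leu, Met,
Phe and Trp are targets: these are the strongly buried hydrophobics;
Cys is excluded because it may form disulphides or coordinate metals,
so mutating it can abolish function outright rather than create a
temperature-conditional fold.

## Sequence rule

For a position *i*, the window of size *w* (odd; default 5 = target ±2)
contributes two statistics under a hydrophobicity scale *H*:

* mean hydrophobicity ⟨H⟩ = mean of scale values over the window;
* hydrophobic moment μH = |Σₙ H(n)(cos nδ, sin nδ)| with angular period
  δ (default 100°, the α-helical twist). For a uniform window the sum
  collapses to the Dirichlet kernel H·|sin(wδ/2)/sin(δ/2)|, which the
  tests use as an independent closed-form oracle.

A target residue is called buried when ⟨H⟩ ≥ τ_H **and** μH ≤ τ_μ:
burial requires a uniformly hydrophobic neighbourhood, whereas a large
moment at helical periodicity marks an amphipathic, surface-facing
environment.

Defaults: Rose mean-fractional-buried-area scale (bundled; pluggable),
w = 5, δ = 100°, τ_H = 0.78, τ_μ = 1.10. The thresholds were fixed once
from the scale's structure: the scale averages ≈ 0.73 over the 20
residues, a window of strongly buried hydrophobics averages ≥ ~0.80,
and a uniform window of the most hydrophobic residues has
μH ≈ 1.227·H ≈ 1.05 at w = 5, δ = 100°, so τ_μ = 1.10 admits uniform
hydrophobic stretches while τ_H = 0.78 rejects windows diluted by polar
residues. The intended calibration target for these free parameters is
the CcdB case-study prediction list, which requires the 3VUB structure;
on hosts with network access the acceptance tests check the defaults
against it directly. Terminal windows are truncated by default
(`terminal_policy="truncate"`) so terminal residues remain scoreable;
`"skip"` restores full-window-only scoring. Ambiguous letters (B, Z, X)
take the scale mean and are never themselves predicted.

## Depth protocol

Residue depth is the distance to the closest **bulk** water, a graded
burial measure that, unlike surface accessibility, keeps resolving
differences well inside the core:

1. **Solvate** — candidate waters on a cubic lattice (spacing 2.8 Å,
   roughly bulk-water density) filling the protein bounding box plus a
   10 Å margin; each cycle applies a random rigid rotation and sub-cell
   offset to the lattice (seeded per (seed, cycle)).
2. **Clash filter** — drop waters closer than 2.6 Å to any protein heavy
   atom (hydrogens are ignored throughout).
3. **Bulk filter** — iteratively remove waters with fewer than 2 water
   neighbours within 4.2 Å until a fixed point; this deletes waters
   trapped in cavities and grooves, which must not terminate depth
   measurements. The pruning operator is monotone (a subset of waters
   can only lose neighbours), so the fixed point is well defined and
   adding protein atoms can never decrease an existing atom's depth —
   a property the tests verify exactly by solvating nested clusters
   from a shared candidate lattice.
4. **Depths** — per-atom nearest-water distance via a k-d tree (equal,
   and tested equal, to exhaustive search); per-residue mean over all
   heavy atoms (side-chain-only mean available by flag, with an
   all-atom fallback for glycine); mean and SD across 25 cycles.

The jittered lattice replaces a pre-equilibrated molecular-dynamics
water box: cycle averaging plays the role of box re-orientation, and the
across-cycle SD of an exposed residue stays below one lattice spacing.
Numerical floors/ceilings follow from the construction: no depth can be
below the clash cutoff, and a fully exposed atom's depth is bounded by
clash cutoff + √3·spacing.

Structures are read from PDB text with gemmi: first model only, altlocs
resolved to the highest-occupancy conformer (ties: first encountered),
waters and non-polymer ligands dropped, hetero amino acids (e.g. MSE)
kept but mapped to 'X' in sequences. When REMARK 350 BIOMT operators are
present the biological unit is built by default before depth
computation — burial is only meaningful in the functional oligomer —
with symmetry copies given suffixed chain identifiers and unchanged
author numbering. Missing side-chain atoms are not rebuilt; depth is
computed on the atoms present.

## Structure rule

A residue whose mean depth **strictly** exceeds its type threshold is
predicted: Val 6.25, Ile 6.75, Leu 6.75, Met 7.00, Phe 7.00, Trp 7.00 Å
(constants corresponding to ~5% mean side-chain accessibility, taken as
given; re-deriving them from a structure corpus is out of scope). The
strict inequality matters at the margin — a Val at exactly 6.25 Å or at
6.18 Å is not called. In assemblies the same author position occurs in
several chains; a position is predicted if **any** copy exceeds the
threshold and reports are collapsed to unique author positions, which
matches how validated positions are tabulated. Thresholds are
overridable per run.

## Combination, model gate, evaluation

The two prediction sets are merged by author position into records
labelled sequence / structure / both (the merge is commutative and
idempotent; conflicting wild-type identities raise an error). When only
a homology model is available, structure-based prediction is allowed
only if externally computed reliability scores pass the gate
GA341 ≥ 0.75 and normalized DOPE ≤ −1 — both boundaries inclusive, a
deliberate resolution of an unspecified strictness; otherwise the
sequence route is used alone. Building the models themselves
(PSI-BLAST/SALIGN/MODELLER) is outside this package; only the gate is
implemented, and it reproduces the 11-accept/4-reject partition of the
15 bundled template scores, where every rejected model stems from a
<25%-identity template.

Evaluation reports coverage (number of predictions) and precision
(validated hits / predictions **with known experimental status**):
predictions never tested experimentally are excluded from the precision
denominator rather than counted as false positives. The Jaccard index
|A∩B|/|A∪B| quantifies between-method overlap; on the published
benchmark cardinalities (34 shared of 57 sequence / 85 structure
predictions) it is 34/108 ≈ 0.315.

## Synthetic fixtures

Three generators make the whole pipeline testable without downloads:

* an ideal α-helix Cα trace (rise 1.5 Å, twist 100°, radius 2.3 Å,
  giving the canonical ~3.8 Å Cα–Cα distance) for the helical
  periodicity assumptions;
* layered clusters — concentric quasi-uniform (golden-spiral) shells of
  single-atom residues typed as standard amino acids, with shell labels:
  by construction inner shells must come out deeper, an oracle for the
  depth engine and, typed as Val, for the full structure pipeline;
* designed core sequences — a background homopolymer with hydrophobic
  residues at chosen positions, an oracle for the sequence rule.

What these do **not** emulate: real side-chain packing, cavities,
surface grooves, crystallographic disorder, or realistic sequence
composition. Passing the synthetic suite therefore establishes the
geometric and logical correctness of the operations, not the field
accuracy of the calibrated thresholds on real proteins; the latter is
exactly what the network-dependent benchmark checks cover when the PDB
entries are reachable.

## Problem sizes and determinism

Unit and property tests use 2–5 solvation cycles, clusters of ≤120
atoms and ≤100-atom random toy systems, chosen so the geometric oracles
stay exhaustive-brute-force; the shipped default of 25 cycles is for
production runs on real structures. All randomness flows through
explicit seeds ((seed, cycle) streams for solvation, a seed per fixture
generator), making every profile bit-reproducible.

## Known limitations

* The sequence-rule thresholds reconstruct a two-threshold buried/not
  boundary; the original rule set may have used burial classes with
  distinct thresholds. A multi-class extension would slot in at
  `predict_buried_sequence`.
* Only one angular period δ is supported (no separate β-strand moment).
* No structure repair: residues with missing atoms are used as-is.
* mmCIF input, ID-based fetching, substitution ranking and
  restrictive/permissive temperature estimation are out of scope.
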