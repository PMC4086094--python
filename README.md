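# tspred

Rational design of temperature-sensitive (Ts) protein mutants.

A Ts mutant behaves like wild type below a permissive temperature and
loses activity above a restrictive one — a reversible, tissue- and
stage-independent switch for studying essential genes. Instead of random
mutagenesis and large-scale screening, `tspred` proposes a small set of
candidate positions: **buried hydrophobic residues**, whose substitution
most reliably destabilizes the folded state. At each predicted position
it suggests the stereochemically diverse substitutions Ala, Trp, Asn,
Asp and Pro (unranked); at least one is likely to confer a Ts phenotype.

Two independent predictors are provided:

* **Sequence-based.** For each residue *i* with window *w* (default 5)
  and hydrophobicity scale *H* (Rose mean fractional buried area):

  - windowed mean hydrophobicity ⟨H⟩ᵢ = (1/w) Σₙ H(n)
  - hydrophobic moment μH(i) = | Σₙ H(n)·(cos nδ, sin nδ) |, δ = 100°
    (α-helical periodicity)

  Position *i* is called buried when ⟨H⟩ᵢ ≥ τ_H and μH(i) ≤ τ_μ — a
  hydrophobic neighbourhood without strong amphipathic asymmetry. Only
  Val, Ile, Leu, Met, Phe and Trp are mutation targets; Cys is excluded
  (disulphides, metal sites).

* **Structure-based.** Residue depth — the distance (Å) of a residue's
  atoms to the nearest *bulk* water after solvating the biological unit
  in a jittered water lattice, removing clashing and trapped
  (non-bulk) waters, and averaging over independent solvation cycles. A
  residue is predicted when its mean depth strictly exceeds its
  type-specific threshold: Val 6.25, Ile 6.75, Leu 6.75, Met 7.00,
  Phe 7.00, Trp 7.00 Å.

Predictions from the two routes are merged and labelled
sequence/structure/both. For homology models, an accept/reject gate on
externally computed reliability scores (accept iff GA341 ≥ 0.75 and
normalized DOPE ≤ −1) decides whether the structure route may be used;
on rejection, prediction falls back to sequence only.

## Worked example

Generate a synthetic layered cluster (concentric shells of single-atom
Val "residues" — inner shells are buried by construction) and run the
structure-based predictor:

```bash
tspred fixtures cluster --n 3 --seed 3 --out cluster.pdb
echo '{"solvation": {"n_cycles": 5, "padding": 8.0}}' > fast.json
tspred predict --pdb cluster.pdb --mode structure --config fast.json --seed 1 --out clrun
```

```
[tspred] structure: 1 chain(s), 120 atoms
[tspred] structure rule: 2 position(s)
[tspred] combined [-]: 2 position(s) -> clrun.predictions.tsv
```

`clrun.predictions.tsv`:

```
position  wildtype  method     suggestions          mean_depth  mean_H  mu_H
29        VAL       structure  ALA,ASN,ASP,PRO,TRP  6.319
32        VAL       structure  ALA,ASN,ASP,PRO,TRP  6.263
```

Two innermost-shell valines exceed the 6.25 Å Val depth threshold and
are proposed as Ts positions, each with the five (here four distinct
non-wild-type) suggested substitutions. The sequence route works the
same way from FASTA:

```bash
tspred fixtures sequence --n 24 > core.fasta
tspred predict --fasta core.fasta --mode sequence --out seqrun
```

which predicts the five central valines of the designed hydrophobic core
(positions 11–15), reporting their windowed mean hydrophobicity
(0.80–0.86) and moment (0.90–1.06). `tspred depth` exposes the depth
engine alone; `tspred eval` scores a predictions TSV against a table of
experimentally validated Ts positions (precision is computed only over
predictions whose experimental status is known).

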