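{
  "description": "E. coli CcdB (101 residues; functional form is a homodimer, PDB 3VUB). Published server prediction lists and experimental Ts-mutant status from saturation mutagenesis, used as regression/evaluation data.",
  "protein_length": 101,
  "sequence_predictions": [
    [17, "PHE"], [18, "VAL"], [33, "VAL"], [34, "LEU"], [50, "LEU"],
    [53, "VAL"], [54, "VAL"], [96, "LEU"], [97, "MET"], [98, "PHE"]
  ],
  "structure_predictions": [
    [5, "VAL"], [17, "PHE"], [18, "VAL"], [20, "VAL"], [32, "MET"],
    [33, "VAL"], [34, "LEU"], [36, "LEU"], [63, "MET"], [68, "MET"],
    [90, "ILE"], [94, "ILE"], [97, "MET"], [98, "PHE"]
  ],
  "false_positive_positions": [53],
  "val54_depth_angstrom": 6.18,
  "notes": "All structure-based predictions and 9 of the 10 sequence-based predictions were experimentally verified as Ts positions; V53 is the single confirmed false positive. V54 (depth 6.18 A) marginally misses the 6.25 A Val threshold."
}
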