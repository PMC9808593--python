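# Residue selection manifest for the curated crystal/NMR structure set.
#
# Quadruplex entries list the tetrad-forming guanosines explicitly
# (overhang and loop nucleotides are excluded); duplex entries use
# "all-complete" — every nucleotide passes here and chain-terminal
# residues drop out later via the completeness filter.
#
# The explicit residue lists are RECONSTRUCTED from the deposited
# sequences assuming single-chain, 1-based numbering on chain A.  They
# are intended to be reviewed (and extended to additional chains of the
# asymmetric unit) against the actual coordinate files being analysed;
# deposited numbering varies between entries.  6QJO holds both a
# right- and a left-handed quadruplex and therefore appears twice with
# disjoint residue lists.  For hybrid sequences whose 5' domain is not a
# parallel quadruplex (6GZ6, 7D5D, 7D5E), only the left-handed (GTG)4
# domain guanosines are listed.  Labels follow the structural class:
# 0 (left-handed) for LHG4 and ZDNA, 1 (right-handed) for RHG4 and BDNA.
entries:
  # ---- left-handed G-quadruplexes -----------------------------------
  - pdb_id: 6FQ2
    structural_class: LHG4
    residues: [[A, 2], [A, 3], [A, 5], [A, 6], [A, 8], [A, 9], [A, 11], [A, 12],
               [A, 15], [A, 17], [A, 18], [A, 20], [A, 21], [A, 23], [A, 24], [A, 26]]
  - pdb_id: 7DFY
    structural_class: LHG4
    residues: [[A, 1], [A, 3], [A, 4], [A, 6], [A, 7], [A, 9], [A, 10], [A, 12]]
  - pdb_id: 4U5M
    structural_class: LHG4
    residues: [[A, 1], [A, 3], [A, 4], [A, 6], [A, 7], [A, 9], [A, 10], [A, 12],
               [A, 15], [A, 17], [A, 18], [A, 20], [A, 21], [A, 23], [A, 24], [A, 26]]
  - pdb_id: 6GZ6
    structural_class: LHG4
    residues: [[A, 17], [A, 19], [A, 20], [A, 22], [A, 23], [A, 25], [A, 26], [A, 28]]
  - pdb_id: 6QJO
    structural_class: LHG4
    residues: [[A, 14], [A, 16], [A, 17], [A, 19], [A, 20], [A, 22], [A, 23], [A, 25]]
  - pdb_id: 6QJO
    structural_class: RHG4
    residues: [[A, 1], [A, 2], [A, 4], [A, 6], [A, 8], [A, 9], [A, 11], [A, 12]]
  - pdb_id: 7D5D
    structural_class: LHG4
    residues: [[A, 15], [A, 17], [A, 18], [A, 20], [A, 21], [A, 23], [A, 24], [A, 26]]
  - pdb_id: 7D5E
    structural_class: LHG4
    residues: [[A, 15], [A, 17], [A, 18], [A, 20], [A, 21], [A, 23], [A, 24], [A, 26]]
  # ---- parallel right-handed G-quadruplexes -------------------------
  - pdb_id: 7KLP
    structural_class: RHG4
    residues: [[A, 2], [A, 3], [A, 4], [A, 8], [A, 9], [A, 10],
               [A, 14], [A, 15], [A, 16], [A, 20], [A, 21], [A, 22]]
  - pdb_id: 6N65
    structural_class: RHG4
    residues: [[A, 2], [A, 3], [A, 4], [A, 6], [A, 7], [A, 9],
               [A, 11], [A, 12], [A, 13], [A, 18], [A, 19], [A, 20]]
  - pdb_id: 3T5E
    structural_class: RHG4
    residues: [[A, 2], [A, 3], [A, 4], [A, 8], [A, 9], [A, 10],
               [A, 14], [A, 15], [A, 16], [A, 20], [A, 21], [A, 22]]
  - pdb_id: 6H5R
    structural_class: RHG4
    residues: [[A, 3], [A, 4], [A, 5], [A, 9], [A, 10], [A, 11],
               [A, 15], [A, 16], [A, 17], [A, 21], [A, 22], [A, 23]]
  - pdb_id: 4FXM
    structural_class: RHG4
    residues: [[A, 2], [A, 3], [A, 4], [A, 8], [A, 9], [A, 10],
               [A, 14], [A, 15], [A, 16], [A, 20], [A, 21], [A, 22]]
  - pdb_id: 2N3M
    structural_class: RHG4
    residues: [[A, 1], [A, 2], [A, 4], [A, 5], [A, 7], [A, 8], [A, 11], [A, 14]]
  # ---- Z-DNA --------------------------------------------------------
  - pdb_id: 3P4J
    structural_class: ZDNA
    residues: all-complete
  - pdb_id: 4OCB
    structural_class: ZDNA
    residues: all-complete
  - pdb_id: 4FS6
    structural_class: ZDNA
    residues: all-complete
  - pdb_id: 4FS5
    structural_class: ZDNA
    residues: all-complete
  - pdb_id: 4HIG
    structural_class: ZDNA
    residues: all-complete
  - pdb_id: 4HIF
    structural_class: ZDNA
    residues: all-complete
  - pdb_id: 7JY2
    structural_class: ZDNA
    residues: all-complete
  - pdb_id: 7ATG
    structural_class: ZDNA
    residues: all-complete
  # ---- B-DNA --------------------------------------------------------
  - pdb_id: 1BNA
    structural_class: BDNA
    residues: all-complete
  - pdb_id: 2BNA
    structural_class: BDNA
    residues: all-complete
  - pdb_id: 3BNA
    structural_class: BDNA
    residues: all-complete
  - pdb_id: 4BNA
    structural_class: BDNA
    residues: all-complete
  - pdb_id: 5BNA
    structural_class: BDNA
    residues: all-complete
  - pdb_id: 1D60
    structural_class: BDNA
    residues: all-complete
  - pdb_id: 1SGS
    structural_class: BDNA
    residues: all-complete
  - pdb_id: 1DC0
    structural_class: BDNA
    residues: all-complete
  - pdb_id: 1D8G
    structural_class: BDNA
    residues: all-complete
  - pdb_id: 5DNB
    structural_class: BDNA
    residues: all-complete
  - pdb_id: 436D
    structural_class: BDNA
    residues: all-complete
  - pdb_id: 4C64
    structural_class: BDNA
    residues: all-complete
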