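# Minimal model-compound charge/radius library (synthetic stand-in set).
#
# Purpose: assign per-atom partial charges and van der Waals radii to plain
# PDB input for the 20 standard amino acids, and define the charge states of
# titratable groups.  The set is deliberately compact: charge is placed on
# the chemically relevant group atoms (amide backbone, carboxylates, amines,
# guanidinium, imidazole, indole) and elsewhere set to zero.  It is NOT a
# force-field charge set; users with real parameter files should supply PQR
# input instead.  The Trp/Trp+ radical-cation distribution in particular is
# a synthetic stand-in spread over the nine indole heavy atoms.

radii:        # Bondi-style vdW radii by element, Å
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  default: 1.70

backbone:     # peptide-unit charges applied to every standard residue
  N: -0.47
  H: 0.31
  HN: 0.31
  CA: 0.07
  HA: 0.09
  C: 0.51
  O: -0.51
  OXT: -0.51

# Default (pH-7-typical) side-chain charges used when a residue is treated
# as non-titrating background.  Atoms not listed carry zero charge.
sidechain:
  ASP: {OD1: -0.5, OD2: -0.5}
  GLU: {OE1: -0.5, OE2: -0.5}
  LYS: {NZ: 1.0}
  ARG: {NH1: 0.5, NH2: 0.5}
  HIS: {}          # neutral singly-protonated by default
  CYS: {}
  TYR: {}
  SER: {}
  THR: {}
  ASN: {}
  GLN: {}
  TRP: {}
  PHE: {}
  ALA: {}
  GLY: {}
  VAL: {}
  LEU: {}
  ILE: {}
  MET: {}
  PRO: {}

# Titratable-group definitions: member atoms and per-state charge vectors.
# State 0 is the reference state of the microstate model (deprotonated for
# acids/bases, reduced for redox couples, fully protonated cation for His).
# Successive states differ from the reference by exactly one proton or one
# electron (total charge difference +-1 e).
sites:
  ASP:
    kind: acid
    pka_ref: 4.0
    members: [CG, OD1, OD2]
    states:
      deprotonated: {OD1: -0.5, OD2: -0.5}
      protonated: {}
  GLU:
    kind: acid
    pka_ref: 4.4
    members: [CD, OE1, OE2]
    states:
      deprotonated: {OE1: -0.5, OE2: -0.5}
      protonated: {}
  CYS:
    kind: acid
    pka_ref: 9.5
    members: [SG]
    states:
      deprotonated: {SG: -1.0}
      protonated: {}
  TYR:
    kind: acid
    pka_ref: 9.6
    members: [OH, CZ]
    states:
      deprotonated: {OH: -1.0}
      protonated: {}
  LYS:
    kind: base
    pka_ref: 10.4
    members: [NZ]
    states:
      deprotonated: {}
      protonated: {NZ: 1.0}
  ARG:
    kind: base
    pka_ref: 12.0
    members: [CZ, NH1, NH2]
    states:
      deprotonated: {}
      protonated: {NH1: 0.5, NH2: 0.5}
  HIS:
    kind: his_tautomer
    pka_ref_epsilon: 7.0      # deprotonation at N-epsilon -> N-delta-H tautomer
    pka_ref_delta: 6.6        # deprotonation at N-delta  -> N-epsilon-H tautomer
    members: [CG, ND1, CD2, CE1, NE2]
    states:
      cation: {ND1: 0.5, NE2: 0.5}
      delta_protonated: {ND1: 0.25, NE2: -0.25}
      epsilon_protonated: {ND1: -0.25, NE2: 0.25}
  TRP:
    kind: redox
    em_ref_mv: 1070.0         # Trp/Trp+ one-electron couple in water
    members: [CG, CD1, CD2, NE1, CE2, CE3, CZ2, CZ3, CH2]
    states:
      reduced: {}
      oxidized: {NE1: 0.28, CD1: 0.12, CG: 0.10, CE2: 0.14, CD2: 0.10,
                 CE3: 0.06, CZ2: 0.08, CZ3: 0.06, CH2: 0.06}
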