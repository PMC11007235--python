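# Default per-atom physical annotation tables.
#
# Charges are formal charges split symmetrically over chemically equivalent
# atoms (carboxylates -0.5 per oxygen, guanidinium +0.5 per NH group,
# ammonium +1 on NZ); histidine is neutral by default.  Radii are a single
# per-element van der Waals table.  Everything here is config-overridable.

radii:  # Angstrom, per element
  H: 1.10
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80

charges:  # elementary charge units, per (residue, atom name); others are 0
  ASP: {OD1: -0.5, OD2: -0.5}
  GLU: {OE1: -0.5, OE2: -0.5}
  LYS: {NZ: 1.0}
  ARG: {NH1: 0.5, NH2: 0.5}

# heavy atoms able to accept a hydrogen bond; backbone O/OXT are acceptors
# for every residue type
acceptors:
  _backbone: [O, OXT]
  ASP: [OD1, OD2]
  GLU: [OE1, OE2]
  ASN: [OD1]
  GLN: [OE1]
  SER: [OG]
  THR: [OG1]
  TYR: [OH]
  HIS: [ND1]
  MET: [SD]

# heavy atoms that carry at least one polar hydrogen (donor heavy atoms);
# backbone N (except proline) is a donor for every residue type
donors:
  _backbone: [N]
  SER: [OG]
  THR: [OG1]
  TYR: [OH]
  LYS: [NZ]
  ARG: [NE, NH1, NH2]
  ASN: [ND2]
  GLN: [NE2]
  HIS: [NE2]
  TRP: [NE1]
  CYS: [SG]

backbone_atoms: [N, CA, C, O, OXT, H, HA, H2, H3]

# atoms forming rigid planar groups; intra-group pairs are excluded from
# clash statistics and clash energy
rigid_groups:
  PHE: [[CG, CD1, CD2, CE1, CE2, CZ]]
  TYR: [[CG, CD1, CD2, CE1, CE2, CZ, OH]]
  TRP: [[CG, CD1, CD2, NE1, CE2, CE3, CZ2, CZ3, CH2]]
  HIS: [[CG, ND1, CD2, CE1, NE2]]
  ARG: [[NE, CZ, NH1, NH2]]
  ASP: [[CG, OD1, OD2]]
  GLU: [[CD, OE1, OE2]]
  ASN: [[CG, OD1, ND2]]
  GLN: [[CD, OE1, NE2]]

# per-residue energy coefficients, kcal/mol
#
# solvation_hydrophobic: cost of exposing apolar surface (>= 0, destabilizing
#   when exposed), from water/octanol-type side-chain transfer scales.
# solvation_polar: gain of exposing polar groups to water (<= 0).
# vdw: packing stabilization realized in proportion to burial (<= 0).
# sidechain_entropy: conformational entropy cost of immobilizing the side
#   chain (>= 0), from empirical side-chain entropy scales.
coefficients:
  ALA: {hydrophobic: 0.31, polar:  0.00, vdw: -0.50, entropy: 0.00}
  ARG: {hydrophobic: 0.00, polar: -1.01, vdw: -1.40, entropy: 2.03}
  ASN: {hydrophobic: 0.00, polar: -0.60, vdw: -0.90, entropy: 1.57}
  ASP: {hydrophobic: 0.00, polar: -0.77, vdw: -0.90, entropy: 1.25}
  CYS: {hydrophobic: 1.54, polar:  0.00, vdw: -0.80, entropy: 1.22}
  GLN: {hydrophobic: 0.00, polar: -0.22, vdw: -1.10, entropy: 2.02}
  GLU: {hydrophobic: 0.00, polar: -0.64, vdw: -1.10, entropy: 1.65}
  GLY: {hydrophobic: 0.00, polar:  0.00, vdw: -0.30, entropy: 0.00}
  HIS: {hydrophobic: 0.13, polar: -0.40, vdw: -1.20, entropy: 0.99}
  ILE: {hydrophobic: 1.80, polar:  0.00, vdw: -1.30, entropy: 0.75}
  LEU: {hydrophobic: 1.70, polar:  0.00, vdw: -1.30, entropy: 0.75}
  LYS: {hydrophobic: 0.00, polar: -0.99, vdw: -1.20, entropy: 1.94}
  MET: {hydrophobic: 1.23, polar:  0.00, vdw: -1.30, entropy: 1.51}
  PHE: {hydrophobic: 1.79, polar:  0.00, vdw: -1.50, entropy: 0.58}
  PRO: {hydrophobic: 0.72, polar:  0.00, vdw: -0.90, entropy: 0.00}
  SER: {hydrophobic: 0.00, polar: -0.30, vdw: -0.60, entropy: 1.71}
  THR: {hydrophobic: 0.26, polar: -0.26, vdw: -0.80, entropy: 1.63}
  TRP: {hydrophobic: 2.25, polar:  0.00, vdw: -1.90, entropy: 0.97}
  TYR: {hydrophobic: 0.96, polar: -0.30, vdw: -1.60, entropy: 0.99}
  VAL: {hydrophobic: 1.22, polar:  0.00, vdw: -1.00, entropy: 0.50}
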