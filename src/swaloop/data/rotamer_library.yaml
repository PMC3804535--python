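# Coarse backbone-independent side-chain rotamer library (version 1).
#
# For each residue type, chi_values lists the candidate values (degrees) per
# chi angle; canonical rotamers are the Cartesian product of these lists
# (gauche+/trans/gauche- for sp3 torsions, in-plane candidates for terminal
# sp2 torsions).  sigma gives the per-chi standard deviation used for the
# +/- 1 sigma expansion of chi1 and chi2 applied on top of every canonical
# rotamer.  Residues without chi angles (GLY, ALA, PRO) have exactly one
# (empty) rotamer.

version: 1
sigma_default: 10.0

chi_values:
  SER: [[-60, 60, 180], [-60, 60, 180]]
  CYS: [[-60, 60, 180]]
  THR: [[-60, 60, 180], [-60, 60, 180]]
  VAL: [[-60, 60, 180]]
  LEU: [[-60, 60, 180], [-60, 60, 180]]
  ILE: [[-60, 60, 180], [-60, 60, 180]]
  MET: [[-60, 60, 180], [-60, 60, 180], [-60, 60, 180]]
  PHE: [[-60, 60, 180], [-90, -30, 30, 90]]
  TYR: [[-60, 60, 180], [-90, -30, 30, 90]]
  TRP: [[-60, 60, 180], [-90, -30, 30, 90]]
  ASP: [[-60, 60, 180], [-60, 0, 60]]
  GLU: [[-60, 60, 180], [-60, 60, 180], [-60, 0, 60]]
  ASN: [[-60, 60, 180], [-90, -30, 30, 90]]
  GLN: [[-60, 60, 180], [-60, 60, 180], [-90, -30, 30, 90]]
  LYS: [[-60, 60, 180], [-60, 60, 180], [-60, 60, 180], [-60, 60, 180]]
  ARG: [[-60, 60, 180], [-60, 60, 180], [-60, 60, 180], [-90, 90, 180]]
  HIS: [[-60, 60, 180], [-90, -30, 30, 90]]
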