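# Atom parameters for the surrogate packing and hydrogen-bond terms
# (version 1).
#
# radius: effective van der Waals radius per element (Angstrom), used as
#   r_min(i,j) = radius_i + radius_j for the split Lennard-Jones term.
# epsilon: uniform pair well depth (energy units; 1 unit ~ 1 kBT).
# rep_cap_fraction: below rep_cap_fraction * r_min the repulsive branch is
#   continued linearly so grid-sampled clashes score poorly but finitely.
# acceptor_exceptions: nitrogen acceptors (element N is otherwise a donor
#   heavy atom only); all oxygens accept.

version: 1

radius:
  C: 1.75
  N: 1.55
  O: 1.50
  S: 1.80

epsilon: 0.20
rep_cap_fraction: 0.6
pair_cutoff: 6.0

hbond:
  heavy_cutoff: 3.2      # hard zero beyond this donor-acceptor distance
  well_center: 2.9
  well_sigma: 0.25
  switch_width: 0.3      # smooth switch-off approaching heavy_cutoff

acceptor_exceptions:
  - [HIS, ND1]
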