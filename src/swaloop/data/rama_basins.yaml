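# Backbone-torsion (Ramachandran) score construction parameters (version 1).
#
# Each residue class gets a 20-degree-binned (phi, psi) table built at load
# time from a mixture of periodic Gaussian basins:
#
#   p(phi, psi) = sum_b w_b * exp(-0.5 * (d_phi/s_phi)^2 - 0.5 * (d_psi/s_psi)^2) + floor
#   score(phi, psi) = min( -log(p / p_max), cap ) + shift
#
# with angular differences taken on the circle.  The shift places the table
# minimum at `shift` (<= 0); the sampling filter threshold of 0.8 energy
# units then retains the canonical basin cores while rejecting disallowed
# regions.  The construction is fully self-contained: basins encode textbook
# alpha / beta / left-handed-alpha (and proline / pre-proline) regions and
# are not fit to any external data set.
#
# basin fields: [phi0, psi0, sigma_phi, sigma_psi, weight]

version: 1
grid_step: 20
floor: 1.0e-4
cap: 8.0
shift: -1.0

classes:
  generic:
    - [-63, -43, 15, 17, 1.0]
    - [-115, 130, 25, 25, 1.0]
    - [60, 45, 13, 13, 0.15]
  glycine:
    - [-63, -41, 20, 20, 1.0]
    - [63, 41, 20, 20, 1.0]
    - [-90, 170, 30, 25, 1.0]
    - [90, -170, 30, 25, 1.0]
  proline:
    - [-63, -35, 11, 14, 1.0]
    - [-63, 145, 11, 15, 1.0]
  preproline:
    - [-63, -43, 14, 16, 0.8]
    - [-125, 125, 25, 25, 1.2]
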