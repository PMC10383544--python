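# Refractive index n and static dielectric constant eps for water and
# water-cosolvent mixtures at 25 degC, used to evaluate the Lippert-Mataga
# orientation-polarizability factor deltaf(n, eps).
#
# Values are representative literature numbers for binary aqueous mixtures:
# water from CRC Handbook (n_D at 589 nm, eps at 25 degC); glycerol-water and
# sucrose-water interpolated from standard refractometric/dielectric tables
# of the binary systems.  Users with measured (n, eps) for their buffers
# should supply those instead.
water:
  n: 1.3325
  eps: 78.36
glycerol:
  # mass_fraction_percent: {n, eps}
  40.0: {n: 1.384, eps: 68.8}
  50.0: {n: 1.398, eps: 64.0}
sucrose:
  30.0: {n: 1.381, eps: 72.0}
  37.0: {n: 1.393, eps: 69.5}
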