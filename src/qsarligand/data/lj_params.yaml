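# Lennard-Jones well depths (kcal/mol) per element for the steric probe
# field, combined with the Van der Waals radii (vdw_radii.yaml) by
# Lorentz-Berthelot rules: r_min_ij = R_i + R_probe, eps_ij = sqrt(e_i*e_p).
# Well depths follow the AMBER/GAFF order of magnitude. The probe is a
# carbon atom of radius 1.73 Angstrom.
epsilon:
  H: 0.0157
  B: 0.0950
  C: 0.0860
  N: 0.1700
  O: 0.2100
  F: 0.0610
  Si: 0.4000
  P: 0.2000
  S: 0.2500
  Cl: 0.2650
  Br: 0.3200
  I: 0.4000
probe:
  radius: 1.73
  epsilon: 0.1094
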