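# Geometric interaction-typing rules (distances in Angstrom).
# These thresholds are choices of this package's built-in detector; they are
# conventional values, not parameters taken from any external contact tool.
capture_radius: 5.0
vdw_slack: 0.5          # vdW contact if d <= r_vdw(a) + r_vdw(b) + slack
covalent_slack: 0.2     # covalent if d <  r_cov(a) + r_cov(b) + slack
hydrogen_bond_max: 3.5  # donor-class to acceptor-class heavy atoms
hydrophobic_max: 4.5    # two hydrophobic-class carbons
aromatic_max: 5.0       # both atoms in aromatic ring systems (also typed "ring")
polar_max: 4.0          # both atoms donor/acceptor/charged
halogen_max: 4.0        # halogen atom to acceptor-class atom
metal_max: 3.0          # metal HETATM to N/O/S
carbonyl_max: 3.6       # two backbone carbonyl carbons
vdw_radii:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  F: 1.47
  Cl: 1.75
  Br: 1.85
  I: 1.98
  Se: 1.90
  Zn: 1.39
  Mg: 1.73
  Ca: 2.31
  Fe: 1.94
  Na: 2.27
  K: 2.75
  Mn: 1.97
  Cu: 1.40
  Ni: 1.63
  Co: 1.92
covalent_radii:
  H: 0.31
  C: 0.76
  N: 0.71
  O: 0.66
  S: 1.05
  P: 1.07
  F: 0.57
  Cl: 1.02
  Br: 1.20
  I: 1.39
  Se: 1.20
  Zn: 1.22
  Mg: 1.41
  Ca: 1.76
  Fe: 1.32
  Na: 1.66
  K: 2.03
  Mn: 1.39
  Cu: 1.32
  Ni: 1.24
  Co: 1.26
metals: [Zn, Mg, Ca, Fe, Na, K, Mn, Cu, Ni, Co]
halogens: [F, Cl, Br, I]
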