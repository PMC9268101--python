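# Single-bond covalent radii in Angstrom (Cordero et al., Dalton Trans. 2008).
# Reference bond length r_ij between two atoms is taken as the sum of their
# covalent radii; the per-bond-order correction c_ij (0 single / 0.1 aromatic /
# 0.2 double / 0.3 triple) is subtracted from r_ij in the VSA overlap term.
H: 0.31
B: 0.84
C: 0.76
N: 0.71
O: 0.66
F: 0.57
Si: 1.11
P: 1.07
S: 1.05
Cl: 1.02
Br: 1.20
I: 1.39
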