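# Bond dipole moments in Debye used to weight the diagonal of the edge
# adjacency matrix. Values are textbook group dipole moments (Smyth,
# "Dielectric Behavior and Structure", 1955; Minkin et al., "Dipole Moments
# in Organic Chemistry", 1970) — a documented stand-in, since no open
# reference table exists for this descriptor family. Keys are
# "El1-El2:order" with elements alphabetically sorted and order one of
# 1, 1.5, 2, 3. Unlisted bond types contribute 0 (warned at run time).
C-C:1: 0.0
C-C:1.5: 0.0
C-C:2: 0.0
C-C:3: 0.0
C-N:1: 0.22
C-N:1.5: 0.45
C-N:2: 1.90
C-N:3: 3.50
C-O:1: 0.74
C-O:1.5: 0.95
C-O:2: 2.30
C-F:1: 1.41
C-Cl:1: 1.46
C-Br:1: 1.38
C-I:1: 1.19
C-S:1: 0.90
C-S:1.5: 0.90
C-S:2: 2.00
N-N:1: 0.0
N-N:1.5: 0.30
N-N:2: 0.0
N-O:1: 0.30
N-O:1.5: 1.40
N-O:2: 2.00
O-S:2: 2.93
N-S:1: 0.60
F-N:1: 0.60
Cl-N:1: 0.55
Br-N:1: 0.50
F-O:1: 0.40
Cl-O:1: 0.70
O-P:1: 0.80
O-P:2: 2.70
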