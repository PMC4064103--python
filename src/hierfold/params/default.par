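# hierfold default energy parameter set
#
# Self-contained nearest-neighbour test set, kcal/mol.  The scalar block
# carries the DP09-style pseudoknot constants; the loop tables are a compact
# symmetric stack table plus size-indexed loop initiation tables.  Special
# hairpin bonuses, bulge-of-1 stacking and helix-end penalties are
# deliberately omitted (the loader leaves hooks for richer tables).

[constants]
P_s   = -1.38   # exterior pseudoloop initiation
P_sm  = 10.07   # pseudoknot inside a multiloop
P_sp  = 15.00   # pseudoknot inside a pseudoloop
P_b   = 2.46    # band penalty
P_up  = 0.06    # unpaired base in a pseudoloop
P_ps  = 0.96    # closed subregion inside a pseudoloop
a  = 3.39       # multiloop initiation
b  = 0.03       # multiloop base pair
c  = 0.02       # multiloop unpaired base
a_prime = 3.41  # band-spanning multiloop initiation
b_prime = 0.56  # band-spanning multiloop base pair
c_prime = 0.12  # band-spanning multiloop unpaired base
band_stack_factor    = 0.89
band_internal_factor = 0.74
# generic loop-table controls
min_hairpin_unpaired = 3
internal_asymmetry   = 0.50
asymmetry_max        = 3.00
loop_extrapolation   = 1.08

[stack]
# outer pair (bases at i, j), inner pair (bases at i+1, j-1), kcal/mol
# symmetric: e(XY/ZW) == e(WZ/YX)
AU AU  -0.90
AU CG  -2.20
AU GC  -2.10
AU GU  -0.60
AU UA  -1.10
AU UG  -1.40
CG AU  -2.10
CG CG  -3.30
CG GC  -2.40
CG GU  -1.40
CG UA  -2.10
CG UG  -2.10
GC AU  -2.40
GC CG  -3.40
GC GC  -3.30
GC GU  -1.80
GC UA  -2.20
GC UG  -2.50
GU AU  -1.30
GU CG  -2.50
GU GC  -2.10
GU GU  -0.50
GU UA  -1.40
GU UG   1.30
UA AU  -1.30
UA CG  -2.40
UA GC  -2.10
UA GU  -1.00
UA UA  -0.90
UA UG  -1.30
UG AU  -1.00
UG CG  -1.80
UG GC  -1.40
UG GU   0.30
UG UA  -0.60
UG UG  -0.50

[hairpin_loop]
# unpaired bases in the loop -> initiation, kcal/mol
3 5.40
4 5.60
5 5.70
6 5.80
7 5.90
8 6.00
9 6.10

[bulge_loop]
1 3.80
2 2.80
3 3.20
4 3.60
5 4.00
6 4.40

[internal_loop]
# total unpaired bases (both sides) -> initiation, kcal/mol
2 1.50
3 1.60
4 1.70
5 1.80
6 2.00
7 2.20
8 2.30
9 2.40
10 2.50
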