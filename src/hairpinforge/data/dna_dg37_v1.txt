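# hairpinforge DNA folding free-energy tables, version 1
# All values are Delta-G at 37 C, 1 M Na+, in kcal/mol.
# Curated set: unified Watson-Crick nearest-neighbor stack values;
# hairpin/bulge loop-size and terminal-mismatch tables from the 2004 DNA
# compilation; internal-loop size table from the mfold-3.0 DNA line;
# stable GNA-triloop bonus.  Sources and the reasoning behind the mix are
# described in docs/methods.md.

[stack]
# 5'XY3'/3'X'Y'5' Watson-Crick stacks (10 unique values; the remaining six
# orientations follow by rotational symmetry).
AA -1.00
AT -0.88
TA -0.58
CA -1.45
GT -1.44
CT -1.28
GA -1.30
CG -2.17
GC -2.24
GG -1.84

[hairpin]
# loop size : penalty
3 3.4
4 3.4
5 3.5
6 4.2
7 4.2
8 4.2
9 4.3
10 4.4
11 4.5
12 4.6
13 4.7
14 4.8
15 5.0
16 5.1
17 5.2
18 5.3
19 5.4
20 5.5
21 5.6
22 5.7
23 5.8
24 5.9
25 6.0
26 6.1
27 6.2
28 6.3
29 6.4
30 6.5

[bulge]
1 2.9
2 2.3
3 2.5
4 2.7
5 3.0
6 3.2
7 3.4
8 3.5
9 3.6
10 3.7
11 3.9
12 3.9
13 4.0
14 4.1
15 4.2
16 4.3
17 4.3
18 4.4
19 4.4
20 4.5
21 4.5
22 4.6
23 4.6
24 4.7
25 4.7
26 4.7
27 4.8
28 4.9
29 4.9
30 4.9

[internal]
# total unpaired size (both sides) : penalty
4 2.5
5 2.7
6 2.9
7 3.1
8 3.2
9 3.4
10 3.5
11 3.6
12 3.7
13 3.8
14 3.9
15 3.9
16 4.0
17 4.1
18 4.1
19 4.2
20 4.2
21 4.3
22 4.3
23 4.4
24 4.4
25 4.5
26 4.5
27 4.6
28 4.6
29 4.6
30 4.7

[mismatch_hairpin]
# closing pair (5'->3') + first mismatch (5' base, 3' base) : bonus.
# Applied to hairpin loops of size >= 4 and at both closures of internal
# loops; absent combinations score 0.
CG A A -1.0
CG A C -0.8
CG A G -0.9
CG C A -0.8
CG C C -0.5
CG C T -0.7
CG G A -1.0
CG G G -0.9
CG G T -1.0
CG T C -0.6
CG T G -0.9
CG T T -0.9
GC A A -1.0
GC A C -0.7
GC A G -0.8
GC C A -1.0
GC C C -0.6
GC C T -0.7
GC G A -1.0
GC G G -1.0
GC G T -0.8
GC T C -0.6
GC T G -0.9
GC T T -0.9
AT A A -0.7
AT A C -0.3
AT A G -0.5
AT C A -0.6
AT C C -0.2
AT C T -0.3
AT G A -0.6
AT G G -0.4
AT G T -0.5
AT T C -0.3
AT T G -0.5
AT T T -0.4
TA A A -0.6
TA A C -0.4
TA A G -0.5
TA C A -0.5
TA C C -0.2
TA C T -0.5
TA G A -0.6
TA G G -0.4
TA G T -0.5
TA T C -0.3
TA T G -0.6
TA T T -0.3

[triloop_bonus]
# sequence-specific 3-loop bonuses; pattern is the loop only, N = any base
GNA -1.0

[multiloop]
# offset, per-branch (closing helix included), per-unpaired-base
offset 3.0
branch 0.2
unpaired 0.2

[ninio]
# internal-loop asymmetry: slope per |n1 - n2|, cap
slope 0.4
max 3.0

[misc]
# Jacobson-Stockmayer extrapolation: dG(n) = dG(30) + js_coef * ln(n/30)
js_coef 1.50
# helix-terminal A:T penalty at exterior/multiloop helix ends
terminal_at 0.0
temperature_c 37
sodium_molar 1.0
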