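# Approximate per-residue membrane-insertion pseudo-energy well depths
# (kcal/mol; negative = insertion favoured). Coarse parameterization of a
# depth-dependent Ez-style potential; override via config for other sets.
A	-0.5
C	-0.3
D	1.2
E	1.1
F	-1.1
G	-0.2
H	0.8
I	-1.0
K	1.3
L	-1.2
M	-0.9
N	0.9
P	0.3
Q	0.9
R	1.4
S	0.1
T	0.0
V	-0.9
W	-0.6
Y	-0.3
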