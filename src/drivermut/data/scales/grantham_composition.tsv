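residue	value
A	0
C	2.75
D	1.38
E	0.92
F	0
G	0.74
H	0.58
I	0
K	0.33
L	0
M	0
N	1.33
P	0.39
Q	0.89
R	0.65
S	1.42
T	0.71
V	0
W	0.13
Y	0.2
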