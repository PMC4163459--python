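residue	value
A	0.74
C	0.91
D	0.62
E	0.62
F	0.88
G	0.72
H	0.78
I	0.88
K	0.52
L	0.85
M	0.85
N	0.63
P	0.64
Q	0.62
R	0.64
S	0.66
T	0.7
V	0.86
W	0.85
Y	0.76
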