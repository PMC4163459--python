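residue	value
A	0.28
C	0.97
D	-0.52
E	-1.01
F	0.46
G	0.43
H	-0.31
I	0.6
K	-1.62
L	0.6
M	0.43
N	-0.55
P	-0.42
Q	-0.69
R	-1.14
S	-0.19
T	-0.32
V	0.6
W	0.29
Y	-0.15
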