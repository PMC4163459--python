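residue	value
A	89.0932
C	121.158
D	133.103
E	147.129
F	165.189
G	75.0666
H	155.155
I	131.173
K	146.188
L	131.173
M	149.211
N	132.118
P	115.13
Q	146.144
R	174.201
S	105.093
T	119.119
V	117.146
W	204.225
Y	181.189
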