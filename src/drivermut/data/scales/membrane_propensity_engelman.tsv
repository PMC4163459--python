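residue	value
A	-1.6
C	-2
D	9.2
E	8.2
F	-3.7
G	-1
H	3
I	-3.1
K	8.8
L	-2.8
M	-3.4
N	4.8
P	0.2
Q	4.1
R	12.3
S	-0.6
T	-1.2
V	-2.6
W	-1.9
Y	0.7
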