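wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	2	0	0	1	-1	0	0	0	0	0	0	0	-1	0	0	1	0	0	-1	-1
C	0	2	0	0	-1	0	0	0	0	0	0	0	0	0	0	0	0	0	-1	-1
D	0	0	2	1	-1	0	0	-1	0	-1	-1	1	0	0	0	0	0	-1	-1	-1
E	1	0	1	2	-1	0	0	-1	0	-1	-1	0	-1	1	0	0	0	-1	-1	-1
F	-1	-1	-1	-1	2	-1	-1	1	-1	0	0	-1	-1	-1	-1	-1	-1	0	0	1
G	0	0	0	0	-1	2	0	-1	0	-1	-1	0	0	0	0	0	0	-1	-1	-1
H	0	0	0	0	-1	0	2	-1	0	-1	-1	0	0	0	0	0	0	-1	-1	0
I	0	0	-1	-1	1	-1	-1	2	-1	0	0	-1	-1	-1	-1	-1	0	1	0	0
K	0	0	0	0	-1	0	0	-1	2	-1	-1	1	0	0	1	0	0	-1	-1	-1
L	0	0	-1	-1	0	-1	-1	0	-1	2	2	-1	-1	-1	-1	-1	0	1	0	0
M	0	0	-1	-1	0	-1	-1	0	-1	2	2	-1	-1	-1	-1	-1	0	0	0	0
N	0	0	1	0	-1	0	0	-1	1	-1	-1	3	0	1	0	0	0	-1	-1	-1
P	-1	0	0	-1	-1	0	0	-1	0	-1	-1	0	3	0	0	0	0	-1	-1	-1
Q	0	0	0	1	-1	0	0	-1	0	-1	-1	1	0	2	0	0	0	-1	-1	-1
R	0	0	0	0	-1	0	0	-1	1	-1	-1	0	0	0	2	0	0	-1	0	-1
S	1	0	0	0	-1	0	0	-1	0	-1	-1	0	0	0	0	2	0	-1	-1	-1
T	0	0	0	0	-1	0	0	0	0	0	0	0	0	0	0	0	2	0	-1	-1
V	0	0	-1	-1	0	-1	-1	1	-1	1	0	-1	-1	-1	-1	-1	0	2	0	0
W	-1	-1	-1	-1	0	-1	-1	0	-1	0	0	-1	-1	-1	0	-1	-1	0	2	0
Y	-1	-1	-1	-1	1	-1	0	0	-1	0	0	-1	-1	-1	-1	-1	-1	0	0	2
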