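wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	8	1	3	4	1	3	3	2	3	2	3	3	4	3	2	4	3	3	1	1
C	1	9	1	0	0	1	3	1	0	0	3	1	0	0	1	2	2	1	2	1
D	3	1	8	5	1	3	4	1	3	1	2	5	3	4	1	3	3	1	0	1
E	4	0	5	8	0	3	2	1	4	1	1	4	4	5	3	4	4	2	1	2
F	1	0	1	0	9	0	4	3	0	5	5	0	1	0	1	2	1	3	6	6
G	3	1	3	3	0	8	2	1	3	1	1	3	3	2	3	3	2	2	1	0
H	3	3	4	2	4	2	8	2	4	2	3	4	3	4	5	3	4	2	3	4
I	2	1	1	1	3	1	2	8	1	5	5	1	1	0	1	2	3	5	3	3
K	3	0	3	4	0	3	4	1	8	2	1	4	3	4	5	3	3	2	1	1
L	2	0	1	1	5	1	2	5	2	8	6	1	1	3	2	2	3	5	3	3
M	3	3	2	1	5	1	3	5	1	6	8	2	1	3	1	2	3	4	1	2
N	3	1	5	4	0	3	4	1	4	1	2	8	1	4	3	5	3	1	0	2
P	4	0	3	4	1	3	3	1	3	1	1	1	8	3	3	3	3	2	0	0
Q	3	0	4	5	0	2	4	0	4	3	3	4	3	8	5	4	3	2	2	1
R	2	1	1	3	1	3	5	1	5	2	1	3	3	5	8	4	3	2	3	2
S	4	2	3	4	2	3	3	2	3	2	2	5	3	4	4	8	5	2	3	3
T	3	2	3	4	1	2	4	3	3	3	3	3	3	3	3	5	8	3	2	1
V	3	1	1	2	3	2	2	5	2	5	4	1	2	2	2	2	3	8	2	3
W	1	2	0	1	6	1	3	3	1	3	1	0	0	2	3	3	2	2	9	6
Y	1	1	1	2	6	0	4	3	1	3	2	2	0	1	2	3	1	3	6	9
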