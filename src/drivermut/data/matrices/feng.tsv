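wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	6	2	4	4	2	5	2	2	3	2	2	3	5	3	2	5	5	5	2	2
C	2	6	1	0	3	3	2	2	0	2	2	2	2	1	2	4	2	2	3	3
D	4	1	6	5	1	4	3	1	3	1	0	5	2	4	2	3	2	3	0	2
E	4	0	5	6	0	4	2	1	4	1	1	3	3	4	2	3	3	4	1	1
F	2	3	1	0	6	1	2	4	0	4	2	1	2	1	1	3	1	4	3	5
G	5	3	4	4	1	6	1	2	2	2	1	3	3	2	3	5	2	4	3	2
H	2	2	3	2	2	1	6	1	3	3	1	4	3	4	4	3	2	1	1	3
I	2	2	1	1	4	2	1	6	2	5	4	2	2	1	2	2	3	5	2	3
K	3	0	3	4	0	2	3	2	6	2	2	4	2	4	5	3	4	3	1	1
L	2	2	1	1	4	2	3	5	2	6	5	1	3	2	2	2	2	5	4	3
M	2	2	0	1	2	1	1	4	2	5	6	1	2	2	2	1	3	4	3	2
N	3	2	5	3	1	3	4	2	4	1	1	6	2	3	2	5	4	2	0	3
P	5	2	2	3	2	3	3	2	2	3	2	2	6	3	3	4	4	3	2	2
Q	3	1	4	4	1	2	4	1	4	2	2	3	3	6	3	3	3	2	1	2
R	2	2	2	2	1	3	4	2	5	2	2	2	3	3	6	3	3	2	2	1
S	5	4	3	3	3	5	3	2	3	2	1	5	4	3	3	6	5	2	2	3
T	5	2	2	3	1	2	2	3	4	2	3	4	4	3	3	5	6	3	1	2
V	5	2	3	4	4	4	1	5	3	5	4	2	3	2	2	2	3	6	3	3
W	2	3	0	1	3	3	1	2	1	4	3	0	2	1	2	2	1	3	6	3
Y	2	3	2	1	5	2	3	3	1	3	2	3	2	2	1	3	2	3	3	6
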