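wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	5	-1	-2	-1	-3	0	-2	-1	-1	-2	-1	-1	-1	-1	-2	1	0	0	-3	-2
C	-1	13	-4	-3	-2	-3	-3	-2	-3	-2	-2	-2	-4	-3	-4	-1	-1	-1	-5	-3
D	-2	-4	8	2	-5	-1	-1	-4	-1	-4	-4	2	-1	0	-2	0	-1	-4	-5	-3
E	-1	-3	2	6	-3	-3	0	-4	1	-3	-2	0	-1	2	0	-1	-1	-3	-3	-2
F	-3	-2	-5	-3	8	-4	-1	0	-4	1	0	-4	-4	-4	-3	-3	-2	-1	1	4
G	0	-3	-1	-3	-4	8	-2	-4	-2	-4	-3	0	-2	-2	-3	0	-2	-4	-3	-3
H	-2	-3	-1	0	-1	-2	10	-4	0	-3	-1	1	-2	1	0	-1	-2	-4	-3	2
I	-1	-2	-4	-4	0	-4	-4	5	-3	2	2	-3	-3	-3	-4	-3	-1	4	-3	-1
K	-1	-3	-1	1	-4	-2	0	-3	6	-3	-2	0	-1	2	3	0	-1	-3	-3	-2
L	-2	-2	-4	-3	1	-4	-3	2	-3	5	3	-4	-4	-2	-3	-3	-1	1	-2	-1
M	-1	-2	-4	-2	0	-3	-1	2	-2	3	7	-2	-3	0	-2	-2	-1	1	-1	0
N	-1	-2	2	0	-4	0	1	-3	0	-4	-2	7	-2	0	-1	1	0	-3	-4	-2
P	-1	-4	-1	-1	-4	-2	-2	-3	-1	-4	-3	-2	10	-1	-3	-1	-1	-3	-4	-3
Q	-1	-3	0	2	-4	-2	1	-3	2	-2	0	0	-1	7	1	0	-1	-3	-1	-1
R	-2	-4	-2	0	-3	-3	0	-4	3	-3	-2	-1	-3	1	7	-1	-1	-3	-3	-1
S	1	-1	0	-1	-3	0	-1	-3	0	-3	-2	1	-1	0	-1	5	2	-2	-4	-2
T	0	-1	-1	-1	-2	-2	-2	-1	-1	-1	-1	0	-1	-1	-1	2	5	0	-3	-2
V	0	-1	-4	-3	-1	-4	-4	4	-3	1	1	-3	-3	-3	-3	-2	0	5	-3	-1
W	-3	-5	-5	-3	1	-3	-3	-3	-3	-2	-1	-4	-4	-1	-3	-4	-3	-3	15	2
Y	-2	-3	-3	-2	4	-3	2	-1	-2	-1	0	-2	-3	-1	-1	-2	-2	-1	2	8
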