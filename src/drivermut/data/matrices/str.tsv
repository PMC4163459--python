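wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	4	-2	-1	0	-3	0	-2	-2	-1	-2	0	-1	-1	0	-1	0	-1	0	-3	-3
C	-2	11	-7	-3	-2	-6	-6	-4	-4	-6	-5	-6	-8	-3	-2	-4	-5	-4	-6	-6
D	-1	-7	6	2	-5	-1	0	-3	-1	-6	-4	2	-1	0	-2	0	-1	-4	-6	-3
E	0	-3	2	5	-4	-2	-2	-3	1	-4	-2	0	-1	2	0	-1	0	-2	-6	-2
F	-3	-2	-5	-4	7	-6	-2	1	-3	2	0	-3	-5	-4	-4	-3	-3	-1	2	3
G	0	-6	-1	-2	-6	5	-3	-5	-3	-5	-4	-1	-2	-2	-2	-1	-3	-4	-4	-3
H	-2	-6	0	-2	-2	-3	8	-5	0	-3	-2	2	-3	0	0	-2	-2	-2	-3	0
I	-2	-4	-3	-3	1	-5	-5	6	-3	2	1	-3	-4	-5	-3	-3	-2	2	-2	-1
K	-1	-4	-1	1	-3	-3	0	-3	5	-2	-1	0	-1	1	2	-1	0	-3	-3	-2
L	-2	-6	-6	-4	2	-5	-3	2	-2	5	3	-3	-3	-3	-3	-4	-3	1	-1	-2
M	0	-5	-4	-2	0	-4	-2	1	-1	3	8	-2	-6	1	-4	-4	-2	0	-2	-1
N	-1	-6	2	0	-3	-1	2	-3	0	-3	-2	5	-2	0	-1	0	0	-4	-5	-1
P	-1	-8	-1	-1	-5	-2	-3	-4	-1	-3	-6	-2	7	-2	-2	-1	-1	-4	-4	-6
Q	0	-3	0	2	-4	-2	0	-5	1	-3	1	0	-2	6	1	-1	0	-2	-5	-3
R	-1	-2	-2	0	-4	-2	0	-3	2	-3	-4	-1	-2	1	7	0	-1	-3	-2	-1
S	0	-4	0	-1	-3	-1	-2	-3	-1	-4	-4	0	-1	-1	0	4	1	-3	-5	-2
T	-1	-5	-1	0	-3	-3	-2	-2	0	-3	-2	0	-1	0	-1	1	5	-1	-5	-2
V	0	-4	-4	-2	-1	-4	-2	2	-3	1	0	-4	-4	-2	-3	-3	-1	5	-4	-1
W	-3	-6	-6	-6	2	-4	-3	-2	-3	-1	-2	-5	-4	-5	-2	-5	-5	-4	10	2
Y	-3	-6	-3	-2	3	-3	0	-1	-2	-2	-1	-1	-6	-3	-1	-2	-2	-1	2	7
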