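wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	16	11	9	10	10	8	11	9	10	11	11	9	6	11	8	10	10	9	11	9
C	11	16	8	9	10	8	10	8	9	11	10	9	7	10	8	10	10	8	11	10
D	9	8	16	11	4	9	9	3	11	6	5	11	8	11	10	10	9	3	6	7
E	10	9	11	16	6	6	11	4	11	7	8	10	5	11	9	9	8	4	7	6
F	10	10	4	6	16	7	9	12	6	11	10	6	4	7	5	8	10	11	11	10
G	8	8	9	6	7	16	7	6	7	6	4	10	11	8	7	11	10	6	8	10
H	11	10	9	11	9	7	16	8	11	10	10	10	5	11	10	10	10	9	10	9
I	9	8	3	4	12	6	8	16	4	10	9	5	3	6	4	8	10	12	11	10
K	10	9	11	11	6	7	11	4	16	7	8	11	6	12	11	10	9	5	7	7
L	11	11	6	7	11	6	10	10	7	16	11	7	4	9	6	8	9	10	11	9
M	11	10	5	8	10	4	10	9	8	11	16	6	2	9	6	7	8	9	10	8
N	9	9	11	10	6	10	10	5	11	7	6	16	9	11	10	11	10	5	8	8
P	6	7	8	5	4	11	5	3	6	4	2	9	16	7	6	10	8	3	6	8
Q	11	10	11	11	7	8	11	6	12	9	9	11	7	16	10	10	10	6	9	8
R	8	8	10	9	5	7	10	4	11	6	6	10	6	10	16	9	9	5	7	7
S	10	10	10	9	8	11	10	8	10	8	7	11	10	10	9	16	11	8	10	11
T	10	10	9	8	10	10	10	10	9	9	8	10	8	10	9	11	16	10	11	11
V	9	8	3	4	11	6	9	12	5	10	9	5	3	6	5	8	10	16	11	10
W	11	11	6	7	11	8	10	11	7	11	10	8	6	9	7	10	11	11	16	11
Y	9	10	7	6	10	10	9	10	7	9	8	8	8	8	7	11	11	10	11	16
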