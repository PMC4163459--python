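wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	4	-1.9	1	1.3	-2.4	1.2	-2.1	-1.8	-1.9	-2.3	-2	-1.7	0.8	-2.1	-1.6	0.1	0.9	1	-2.2	-2.4
C	-1.9	5.5	-1.6	-3	1.8	1	-1.6	-1.9	-3.2	-1.3	-2.7	-1.5	-1.9	-3.1	0.7	1.5	-1.9	-2.2	4.1	2.6
D	1	-1.6	4.8	3.8	-1.7	1.1	1.7	-2.1	0.3	-2.4	-2.5	1.7	-2.2	0.3	-2.3	-2.1	-2.1	1	-2.9	2.3
E	1.3	-3	3.8	5.7	-2.9	1.4	0.3	-2.3	2	-2.5	-1.8	0.3	-2.1	2	-2	-2.8	-2.1	1.3	-3.2	-0.9
F	-2.4	1.8	-1.7	-2.9	4.5	-1.9	-1.1	1.3	-2.8	2.2	0.5	-1.3	-1.8	-2.1	-1.5	0	-2.1	1	0	2
G	1.2	1	1.1	1.4	-1.9	4.2	-2.2	-2.5	-2.2	-2.2	-2.3	-2.6	-1.8	-2.1	0.8	-0.6	-2.1	1.1	1.4	-1.8
H	-2.1	-1.6	1.7	0.3	-1.1	-2.2	4.7	-1.8	0.6	-0.1	-1.8	1.8	0.7	3.6	3.6	-1.6	-1.8	-2.1	-2.1	2.3
I	-1.8	-1.9	-2.1	-2.3	1.3	-2.5	-1.8	4.1	0.7	1.2	3.3	0.9	-1.6	-1.9	-1.2	-0.5	0.8	1	-2.2	-1.6
K	-1.9	-3.2	0.3	2	-2.8	-2.2	0.6	0.7	5.6	-2	1.6	3.5	-1.5	2.2	-0.2	-1.5	1	-2.1	-3	-0.8
L	-2.3	-1.3	-2.4	-2.5	2.2	-2.2	-0.1	1.2	-2	3.4	1.5	-2.2	0	0.1	-0.4	-1.2	-1.9	1.1	-0.3	-1.6
M	-2	-2.7	-2.5	-1.8	0.5	-2.3	-1.8	3.3	1.6	1.5	5.4	0.1	-1.4	-1.2	-0.4	-1.3	0.7	1	-2	-2.9
N	-1.7	-1.5	1.7	0.3	-1.3	-2.6	1.8	0.9	3.5	-2.2	0.1	4.7	-1.6	0.4	-1.5	-0.3	0.9	-2.2	-3	2.5
P	0.8	-1.9	-2.2	-2.1	-1.8	-1.8	0.7	-1.6	-1.5	0	-1.4	-1.6	3.8	1	0.3	0.4	1.1	-2.1	-1.6	-2.3
Q	-2.1	-3.1	0.3	2	-2.1	-2.1	3.6	-1.9	2.2	0.1	-1.2	0.4	1	5.5	0.3	-2.3	-1.7	-2	-2.3	-0.8
R	-1.6	0.7	-2.3	-2	-1.5	0.8	3.6	-1.2	-0.2	-0.4	-0.4	-1.5	0.3	0.3	2.9	0.3	-0.6	-2.1	1.8	-1.9
S	0.1	1.5	-2.1	-2.8	0	-0.6	-1.6	-0.5	-1.5	-1.2	-1.3	-0.3	0.4	-2.3	0.3	2.6	1	-2.2	0.8	0.3
T	0.9	-1.9	-2.1	-2.1	-2.1	-2.1	-1.8	0.8	1	-1.9	0.7	0.9	1.1	-1.7	-0.6	1	4	-2.2	-2.2	-2.1
V	1	-2.2	1	1.3	1	1.1	-2.1	1	-2.1	1.1	1	-2.2	-2.1	-2	-2.1	-2.2	-2.2	4.1	-2.1	-2.2
W	-2.2	4.1	-2.9	-3.2	0	1.4	-2.1	-2.2	-3	-0.3	-2	-3	-1.6	-2.3	1.8	0.8	-2.2	-2.1	7.5	-0.5
Y	-2.4	2.6	2.3	-0.9	2	-1.8	2.3	-1.6	-0.8	-1.6	-2.9	2.5	-2.3	-0.8	-1.9	0.3	-2.1	-2.2	-0.5	6.5
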