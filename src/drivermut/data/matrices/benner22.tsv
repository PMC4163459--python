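wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	2.5	-1.2	-0.2	-0.3	-3.1	0.8	-1.6	-0.4	-1	-1.7	-0.8	0	0.8	-0.9	-1.2	1.3	1.4	0.4	-5.5	-3.5
C	-1.2	12.6	-3.7	-4.3	-0.1	-1.7	-1.5	-2.4	-3.3	-2.6	-2.5	-1.9	-3.1	-3.3	-1.6	0.3	-1.1	-1.7	0.5	0.6
D	-0.2	-3.7	4.8	3.9	-5.4	0.7	0.3	-4	0.2	-4.9	-3.9	2.4	-1.8	0.6	-1	0.1	-0.7	-3	-6.4	-3
E	-0.3	-4.3	3.9	4.6	-5.7	0.5	-0.2	-3.6	1	-4.4	-3.4	1.2	-1.7	1.7	-0.1	-0.5	-0.9	-2.7	-6.3	-4
F	-3.1	-0.1	-5.4	-5.7	7.7	-5.8	0.3	0.5	-5.1	2.2	0.7	-3.5	-3.4	-3.6	-4.3	-2.2	-2.6	-0.1	0.5	5.9
G	0.8	-1.7	0.7	0.5	-5.8	6.2	-2	-3.8	-1	-4.9	-3.8	0.4	-1.8	-1.4	-0.7	0.6	-0.7	-2.5	-4.5	-4.8
H	-1.6	-1.5	0.3	-0.2	0.3	-2	6.1	-3.2	0.8	-2.1	-2.4	1.4	-0.4	2.4	1.5	-0.5	-1.1	-3	-2.7	3.7
I	-0.4	-2.4	-4	-3.6	0.5	-3.8	-3.2	4.2	-3	2.7	3.1	-2.7	-2.3	-2.7	-3.2	-1.4	0.3	3.6	-4.4	-2.2
K	-1	-3.3	0.2	1	-5.1	-1	0.8	-3	4.4	-3.3	-2	1	-1.6	2.2	3.9	-0.4	-0.4	-2.7	-3.7	-3.6
L	-1.7	-2.6	-4.9	-4.4	2.2	-4.9	-2.1	2.7	-3.3	4.6	3.2	-3.5	-1.3	-2	-2.9	-2.1	-1	2	-1.8	-0.7
M	-0.8	-2.5	-3.9	-3.4	0.7	-3.8	-2.4	3.1	-2	3.2	4.9	-2.6	-2	-1.7	-2.1	-1.5	0.1	2.5	-2.8	-1.8
N	0	-1.9	2.4	1.2	-3.5	0.4	1.4	-2.7	1	-3.5	-2.6	3.3	-1.1	0.5	0.4	1.1	0.5	-2.3	-5.2	-1.2
P	0.8	-3.1	-1.8	-1.7	-3.4	-1.8	-0.4	-2.3	-1.6	-1.3	-2	-1.1	7	-0.1	-1.2	1.1	0.4	-1.7	-5.8	-3.5
Q	-0.9	-3.3	0.6	1.7	-3.6	-1.4	2.4	-2.7	2.2	-2	-1.7	0.5	-0.1	4.2	2.2	-0.6	-0.7	-2.4	-3.3	-1.9
R	-1.2	-1.6	-1	-0.1	-4.3	-0.7	1.5	-3.2	3.9	-2.9	-2.1	0.4	-1.2	2.2	5	-0.5	-0.7	-2.9	-1.1	-2.7
S	1.3	0.3	0.1	-0.5	-2.2	0.6	-0.5	-1.4	-0.4	-2.1	-1.5	1.1	1.1	-0.6	-0.5	2	1.5	-0.9	-3.9	-1.9
T	1.4	-1.1	-0.7	-0.9	-2.6	-0.7	-1.1	0.3	-0.4	-1	0.1	0.5	0.4	-0.7	-0.7	1.5	2.5	0.4	-4.5	-3
V	0.4	-1.7	-3	-2.7	-0.1	-2.5	-3	3.6	-2.7	2	2.5	-2.3	-1.7	-2.4	-2.9	-0.9	0.4	3.7	-4.5	-2.6
W	-5.5	0.5	-6.4	-6.3	0.5	-4.5	-2.7	-4.4	-3.7	-1.8	-2.8	-5.2	-5.8	-3.3	-1.1	-3.9	-4.5	-4.5	15.7	1.5
Y	-3.5	0.6	-3	-4	5.9	-4.8	3.7	-2.2	-3.6	-0.7	-1.8	-1.2	-3.5	-1.9	-2.7	-1.9	-3	-2.6	1.5	9
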