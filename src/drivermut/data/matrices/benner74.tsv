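wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	2.4	0.3	-0.3	-0.1	-2.6	0.6	-1	-0.8	-0.4	-1.4	-0.8	-0.2	0.4	-0.3	-0.8	1.1	0.7	0.1	-4.1	-2.6
C	0.3	11.8	-3.2	-3.2	-0.7	-2	-1.3	-1.2	-2.9	-1.6	-1.2	-1.8	-3.1	-2.6	-2.2	0.1	-0.6	-0.2	-0.9	-0.4
D	-0.3	-3.2	4.8	2.9	-4.7	0.2	0.4	-3.9	0.4	-4.2	-3.2	2.2	-1	0.8	-0.5	0.4	-0.2	-2.9	-5.5	-2.8
E	-0.1	-3.2	2.9	3.7	-4.3	-0.5	0.2	-2.9	1.2	-3.1	-2.2	1	-0.7	1.7	0.3	0.1	-0.2	-2.1	-4.7	-3
F	-2.6	-0.7	-4.7	-4.3	7.2	-5.4	0	0.9	-3.6	2.1	1.3	-3.2	-3.8	-2.8	-3.5	-2.6	-2.2	0.1	3	5.3
G	0.6	-2	0.2	-0.5	-5.4	6.6	-1.6	-4.3	-1.1	-4.6	-3.5	0.4	-1.7	-1.1	-1	0.4	-1	-3.1	-4.1	-4.3
H	-1	-1.3	0.4	0.2	0	-1.6	6.1	-2.3	0.6	-1.9	-1.5	1.2	-1	1.4	1	-0.3	-0.5	-2.1	-1	2.5
I	-0.8	-1.2	-3.9	-2.9	0.9	-4.3	-2.3	4	-2.3	2.8	2.6	-2.8	-2.6	-2	-2.6	-1.8	-0.3	3.2	-2.3	-1
K	-0.4	-2.9	0.4	1.2	-3.6	-1.1	0.6	-2.3	3.4	-2.4	-1.5	0.9	-0.8	1.7	2.9	0	0.1	-1.9	-3.6	-2.4
L	-1.4	-1.6	-4.2	-3.1	2.1	-4.6	-1.9	2.8	-2.4	4.2	2.9	-3.1	-2.2	-1.7	-2.4	-2.2	-1.1	1.9	-0.9	-0.1
M	-0.8	-1.2	-3.2	-2.2	1.3	-3.5	-1.5	2.6	-1.5	2.9	4.5	-2.2	-2.4	-1	-1.8	-1.4	-0.4	1.8	-1.3	-0.5
N	-0.2	-1.8	2.2	1	-3.2	0.4	1.2	-2.8	0.9	-3.1	-2.2	3.6	-1	0.7	0.3	0.9	0.4	-2.2	-4	-1.4
P	0.4	-3.1	-1	-0.7	-3.8	-1.7	-1	-2.6	-0.8	-2.2	-2.4	-1	7.5	-0.2	-0.1	0.5	0.1	-1.9	-5.2	-3.4
Q	-0.3	-2.6	0.8	1.7	-2.8	-1.1	1.4	-2	1.7	-1.7	-1	0.7	-0.2	3	1.6	0.1	-0.1	-1.7	-2.8	-1.8
R	-0.8	-2.2	-0.5	0.3	-3.5	-1	1	-2.6	2.9	-2.4	-1.8	0.3	-0.1	1.6	4.8	-0.2	-0.3	-2.2	-1.6	-2
S	1.1	0.1	0.4	0.1	-2.6	0.4	-0.3	-1.8	0	-2.2	-1.4	0.9	0.5	0.1	-0.2	2.1	1.4	-1	-3.4	-1.9
T	0.7	-0.6	-0.2	-0.2	-2.2	-1	-0.5	-0.3	0.1	-1.1	-0.4	0.4	0.1	-0.1	-0.3	1.4	2.5	0.2	-3.7	-2.1
V	0.1	-0.2	-2.9	-2.1	0.1	-3.1	-2.1	3.2	-1.9	1.9	1.8	-2.2	-1.9	-1.7	-2.2	-1	0.2	3.4	-2.9	-1.4
W	-4.1	-0.9	-5.5	-4.7	3	-4.1	-1	-2.3	-3.6	-0.9	-1.3	-4	-5.2	-2.8	-1.6	-3.4	-3.7	-2.9	14.7	3.6
Y	-2.6	-0.4	-2.8	-3	5.3	-4.3	2.5	-1	-2.4	-0.1	-0.5	-1.4	-3.4	-1.8	-2	-1.9	-2.1	-1.4	3.6	8.1
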