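wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	2.5	-1.7	-0.6	-0.7	-3.2	0.8	-2.1	0.1	-1.9	-1.3	-0.2	0	1.1	-1.7	-1.7	1.4	1.7	0.7	-4.3	-4
C	-1.7	12.1	-3.7	-4.7	-0.1	-1.3	-1.2	-3.6	-2.8	-3.8	-3.7	-1.6	-2.7	-3.2	-0.4	0.9	-1.5	-3.1	1.6	2.6
D	-0.6	-3.7	5.2	4.4	-5.7	0.8	0.1	-4.2	-0.2	-5.3	-4.3	2.5	-2.8	0.6	-1.5	-0.4	-1.2	-3.3	-6.3	-2.3
E	-0.7	-4.7	4.4	5.2	-6.7	0.5	-0.2	-4.1	0.9	-5	-4.1	1.1	-2.6	2.1	-0.4	-1.2	-1.6	-3	-5.6	-4.1
F	-3.2	-0.1	-5.7	-6.7	8.3	-5.7	0.1	0	-6.3	2.4	-0.1	-3.5	-3.2	-4.4	-4.9	-1.8	-2.4	-0.5	-1.6	5.6
G	0.8	-1.3	0.8	0.5	-5.7	5.8	-2.1	-3.4	-1.4	-4.6	-3.7	-0.1	-1.7	-1.6	-0.1	0.8	-0.5	-2.3	-1.7	-4.9
H	-2.1	-1.2	0.1	-0.2	0.1	-2.1	6.1	-3.7	0.9	-2.2	-3.4	1.4	-0.4	3.2	1.8	-0.9	-1.7	-3.8	-2.8	4.4
I	0.1	-3.6	-4.2	-4.1	0	-3.4	-3.7	4.4	-3.8	2.4	4	-2.5	-2	-3.8	-3.8	-1.2	0.7	3.9	-5	-3.3
K	-1.9	-2.8	-0.2	0.9	-6.3	-1.4	0.9	-3.8	5.6	-4.1	-2.9	1	-2.3	2.5	4.3	-1.2	-1.1	-3.8	-1.4	-4
L	-1.3	-3.8	-5.3	-5	2.4	-4.6	-2.2	2.4	-4.1	4.8	-2.9	-3.4	-0.2	-2.4	-3.2	-1.5	-0.4	1.9	-3	-1.6
M	-0.2	-3.7	-4.3	-4.1	-0.1	-3.7	-3.4	4	-2.9	-2.9	4.8	-2.5	-1.8	-3.1	-3	-1.3	0.6	3.3	-4.4	-3.6
N	0	-1.6	2.5	1.1	-3.5	-0.1	1.4	-2.5	1	-3.4	-2.5	3.6	-1.1	0.1	-0.1	1.2	0.5	-2.4	-4.4	-0.9
P	1.1	-2.7	-2.8	-2.6	-3.2	-1.7	-0.4	-2	-2.3	-0.2	-1.8	-1.1	6.5	0.1	-1.3	1.4	0.6	-1.6	-4.8	-3.8
Q	-1.7	-3.2	0.6	2.1	-4.4	-1.6	3.2	-3.8	2.5	-2.4	-3.1	0.1	0.1	5.3	2.5	-1.4	-1.7	-3.5	-2.6	-1.4
R	-1.7	-0.4	-1.5	-0.4	-4.9	-0.1	1.8	-3.8	4.3	-3.2	-3	-0.1	-1.3	2.5	5.1	-0.9	-1.3	-3.7	2	-2.6
S	1.4	0.9	-0.4	-1.2	-1.8	0.8	-0.9	-1.2	-1.2	-1.5	-1.3	1.2	1.4	-1.4	-0.9	2.1	1.5	-0.9	-2.9	-1.8
T	1.7	-1.5	-1.2	-1.6	-2.4	-0.5	-1.7	0.7	-1.1	-0.4	0.6	0.5	0.6	-1.7	-1.3	1.5	2.4	0.6	-2.6	-3.4
V	0.7	-3.1	-3.3	-3	-0.5	-2.3	-3.8	3.9	-3.8	1.9	3.3	-2.4	-1.6	-3.5	-3.7	-0.9	0.6	4	-4.8	-3.8
W	-4.3	1.6	-6.3	-5.6	-1.6	-1.7	-2.8	-5	-1.4	-3	-4.4	-4.4	-4.8	-2.6	2	-2.9	-2.6	-4.8	14.7	-0.3
Y	-4	2.6	-2.3	-4.1	5.6	-4.9	4.4	-3.3	-4	-1.6	-3.6	-0.9	-3.8	-1.4	-2.6	-1.8	-3.4	-3.8	-0.3	9.5
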