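wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	2.2	-1.5	0.2	1.7	0.6	0.6	-0.6	1.7	1.4	1.3	1	1.3	-0.2	1.8	1.5	2	1.9	2	-0.9	0.2
C	-1.5	2.2	-1.7	-1.5	-1.6	-1.7	-1.8	-1.6	-1.6	-1.5	-1.6	-1.6	-1.8	-1.4	-1.5	-1.3	-1.4	-1.4	-1.8	-1.1
D	0.2	-1.7	2.2	1	-0.3	-0.4	-1.3	0	0.1	-0.2	-0.5	0.8	-1.2	0.6	-0.1	0.7	0	0	-1.4	-0.4
E	1.7	-1.5	1	2.2	0.6	0.3	-0.6	1.5	1.4	0.9	0.6	1.4	-0.1	2.1	1.9	1.8	1.6	1.6	-1	0.2
F	0.6	-1.6	-0.3	0.6	2.2	-0.4	-1.1	1	0.1	1	-0.2	0.4	-1.1	0.7	0.4	0.5	0.3	0.8	-0.9	2
G	0.6	-1.7	-0.4	0.3	-0.4	2.2	-1.2	0	-0.1	-0.2	-0.4	0.2	-1.2	0.2	0.1	0.7	0.2	0.1	-1.3	-0.2
H	-0.6	-1.8	-1.3	-0.6	-1.1	-1.2	2.2	-0.8	-1	-0.9	-1.2	-0.3	-1.6	-0.5	-0.4	-0.4	-0.9	-0.7	-1.7	-0.8
I	1.7	-1.6	0	1.5	1	0	-0.8	2.2	1	2.1	0.9	0.9	-0.6	1.4	1.4	1.6	1.6	2.2	-0.7	0.4
K	1.4	-1.6	0.1	1.4	0.1	-0.1	-1	1	2.2	0.7	0.4	1	-0.7	1.7	2.1	1.4	1.2	1.2	-1.1	0.5
L	1.3	-1.5	-0.2	0.9	1	-0.2	-0.9	2.1	0.7	2.2	1.8	0.8	-0.8	1.1	1.2	1.3	1.2	2	-0.8	0.5
M	1	-1.6	-0.5	0.6	-0.2	-0.4	-1.2	0.9	0.4	1.8	2.2	0	-1.2	1.2	1.1	0.6	0.8	0.8	-1.3	-0.2
N	1.3	-1.6	0.8	1.4	0.4	0.2	-0.3	0.9	1	0.8	0	2.2	-1	1.6	1.2	1.9	1.1	1.1	-1.1	-0.1
P	-0.2	-1.8	-1.2	-0.1	-1.1	-1.2	-1.6	-0.6	-0.7	-0.8	-1.2	-1	2.2	-0.6	-0.3	-0.3	-0.5	-0.6	-1.6	-1.2
Q	1.8	-1.4	0.6	2.1	0.7	0.2	-0.5	1.4	1.7	1.1	1.2	1.6	-0.6	2.2	2	1.8	1.7	1.5	-1	0.5
R	1.5	-1.5	-0.1	1.9	0.4	0.1	-0.4	1.4	2.1	1.2	1.1	1.2	-0.3	2	2.2	2	1.9	1.5	-0.8	0.8
S	2	-1.3	0.7	1.8	0.5	0.7	-0.4	1.6	1.4	1.3	0.6	1.9	-0.3	1.8	2	2.2	2.1	1.8	-0.8	0.4
T	1.9	-1.4	0	1.6	0.3	0.2	-0.9	1.6	1.2	1.2	0.8	1.1	-0.5	1.7	1.9	2.1	2.2	1.6	-1	0.3
V	2	-1.4	0	1.6	0.8	0.1	-0.7	2.2	1.2	2	0.8	1.1	-0.6	1.5	1.5	1.8	1.6	2.2	-0.7	0.3
W	-0.9	-1.8	-1.4	-1	-0.9	-1.3	-1.7	-0.7	-1.1	-0.8	-1.3	-1.1	-1.6	-1	-0.8	-0.8	-1	-0.7	2.2	-0.6
Y	0.2	-1.1	-0.4	0.2	2	-0.2	-0.8	0.4	0.5	0.5	-0.2	-0.1	-1.2	0.5	0.8	0.4	0.3	0.3	-0.6	2.2
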