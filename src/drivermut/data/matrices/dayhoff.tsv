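wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.2	-0.2	0	0	-0.4	0.1	-0.1	-0.1	-0.1	-0.2	-0.1	0	0.1	0	-0.2	0.1	0.1	0	-0.6	-0.3
C	-0.2	1.2	-0.5	-0.5	-0.4	-0.3	-0.3	-0.2	-0.5	-0.6	-0.5	-0.4	-0.3	-0.5	-0.4	0	-0.2	-0.2	-0.8	0
D	0	-0.5	0.4	0.3	-0.6	0.1	0.1	-0.2	0	-0.4	-0.3	0.2	-0.1	0.2	-0.1	0	0	-0.2	-0.7	-0.4
E	0	-0.5	0.3	0.4	-0.5	0	0.1	-0.2	0	-0.3	-0.2	0.1	-0.1	0.2	-0.1	0	0	-0.2	-0.7	-0.4
F	-0.4	-0.4	-0.6	-0.5	0.9	-0.5	-0.2	0.1	-0.5	0.2	0	-0.4	-0.5	-0.5	-0.4	-0.3	-0.3	-0.1	0	0.7
G	0.1	-0.3	0.1	0	-0.5	0.5	-0.2	-0.3	-0.2	-0.4	-0.3	0	-0.1	-0.1	-0.3	0.1	0	-0.1	-0.7	-0.5
H	-0.1	-0.3	0.1	0.1	-0.2	-0.2	0.6	-0.2	0	-0.2	-0.2	0.2	0	0.3	0.2	-0.1	-0.1	-0.2	-0.3	0
I	-0.1	-0.2	-0.2	-0.2	0.1	-0.3	-0.2	0.5	-0.2	0.2	0.2	-0.2	-0.2	-0.2	-0.2	-0.1	0	0.4	-0.5	-0.1
K	-0.1	-0.5	0	0	-0.5	-0.2	0	-0.2	0.5	-0.3	0	0.1	-0.1	0.1	0.3	0	0	-0.2	-0.3	-0.4
L	-0.2	-0.6	-0.4	-0.3	0.2	-0.4	-0.2	0.2	-0.3	0.6	0.4	-0.3	-0.3	-0.2	-0.3	-0.3	-0.2	0.2	-0.2	-0.1
M	-0.1	-0.5	-0.3	-0.2	0	-0.3	-0.2	0.2	0	0.4	0.6	-0.2	-0.2	-0.1	0	-0.2	-0.1	0.2	-0.4	-0.2
N	0	-0.4	0.2	0.1	-0.4	0	0.2	-0.2	0.1	-0.3	-0.2	0.2	-0.1	0.1	0	0.1	0	-0.2	-0.4	-0.2
P	0.1	-0.3	-0.1	-0.1	-0.5	-0.1	0	-0.2	-0.1	-0.3	-0.2	-0.1	0.6	0	0	0.1	0	-0.1	-0.6	-0.5
Q	0	-0.5	0.2	0.2	-0.5	-0.1	0.3	-0.2	0.1	-0.2	-0.1	0.1	0	0.4	0.1	-0.1	-0.1	-0.2	-0.5	-0.4
R	-0.2	-0.4	-0.1	-0.1	-0.4	-0.3	0.2	-0.2	0.3	-0.3	0	0	0	0.1	0.6	0	-0.1	-0.2	0.2	-0.4
S	0.1	0	0	0	-0.3	0.1	-0.1	-0.1	0	-0.3	-0.2	0.1	0.1	-0.1	0	0.2	0.1	-0.1	-0.2	-0.3
T	0.1	-0.2	0	0	-0.3	0	-0.1	0	0	-0.2	-0.1	0	0	-0.1	-0.1	0.1	0.3	0	-0.5	-0.3
V	0	-0.2	-0.2	-0.2	-0.1	-0.1	-0.2	0.4	-0.2	0.2	0.2	-0.2	-0.1	-0.2	-0.2	-0.1	0	0.4	-0.6	-0.2
W	-0.6	-0.8	-0.7	-0.7	0	-0.7	-0.3	-0.5	-0.3	-0.2	-0.4	-0.4	-0.6	-0.5	0.2	-0.2	-0.5	-0.6	1.7	0
Y	-0.3	0	-0.4	-0.4	0.7	-0.5	0	-0.1	-0.4	-0.1	-0.2	-0.2	-0.5	-0.4	-0.4	-0.3	-0.3	-0.2	0	1
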