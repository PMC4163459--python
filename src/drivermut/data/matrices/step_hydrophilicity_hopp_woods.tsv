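wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.5	-3.5	-3.5	-2	-0.5	-0	-1.3	-3.5	-1.3	-0.8	-0.7	-0.5	-0.7	-3.5	-0.8	-0.1	-1	-2.9	-1.8
C	-0.5	-0	-4	-4	-1.5	-1	-0.5	-0.8	-4	-0.8	-0.3	-1.2	-1	-1.2	-4	-1.3	-0.6	-0.5	-2.4	-1.3
D	-3.5	-4	-0	-0	-5.5	-3	-3.5	-4.8	-0	-4.8	-4.3	-2.8	-3	-2.8	-0	-2.7	-3.4	-4.5	-6.4	-5.3
E	-3.5	-4	-0	-0	-5.5	-3	-3.5	-4.8	-0	-4.8	-4.3	-2.8	-3	-2.8	-0	-2.7	-3.4	-4.5	-6.4	-5.3
F	-2	-1.5	-5.5	-5.5	-0	-2.5	-2	-0.7	-5.5	-0.7	-1.2	-2.7	-2.5	-2.7	-5.5	-2.8	-2.1	-1	-0.9	-0.2
G	-0.5	-1	-3	-3	-2.5	-0	-0.5	-1.8	-3	-1.8	-1.3	-0.2	-0	-0.2	-3	-0.3	-0.4	-1.5	-3.4	-2.3
H	-0	-0.5	-3.5	-3.5	-2	-0.5	-0	-1.3	-3.5	-1.3	-0.8	-0.7	-0.5	-0.7	-3.5	-0.8	-0.1	-1	-2.9	-1.8
I	-1.3	-0.8	-4.8	-4.8	-0.7	-1.8	-1.3	-0	-4.8	-0	-0.5	-2	-1.8	-2	-4.8	-2.1	-1.4	-0.3	-1.6	-0.5
K	-3.5	-4	-0	-0	-5.5	-3	-3.5	-4.8	-0	-4.8	-4.3	-2.8	-3	-2.8	-0	-2.7	-3.4	-4.5	-6.4	-5.3
L	-1.3	-0.8	-4.8	-4.8	-0.7	-1.8	-1.3	-0	-4.8	-0	-0.5	-2	-1.8	-2	-4.8	-2.1	-1.4	-0.3	-1.6	-0.5
M	-0.8	-0.3	-4.3	-4.3	-1.2	-1.3	-0.8	-0.5	-4.3	-0.5	-0	-1.5	-1.3	-1.5	-4.3	-1.6	-0.9	-0.2	-2.1	-1
N	-0.7	-1.2	-2.8	-2.8	-2.7	-0.2	-0.7	-2	-2.8	-2	-1.5	-0	-0.2	-0	-2.8	-0.1	-0.6	-1.7	-3.6	-2.5
P	-0.5	-1	-3	-3	-2.5	-0	-0.5	-1.8	-3	-1.8	-1.3	-0.2	-0	-0.2	-3	-0.3	-0.4	-1.5	-3.4	-2.3
Q	-0.7	-1.2	-2.8	-2.8	-2.7	-0.2	-0.7	-2	-2.8	-2	-1.5	-0	-0.2	-0	-2.8	-0.1	-0.6	-1.7	-3.6	-2.5
R	-3.5	-4	-0	-0	-5.5	-3	-3.5	-4.8	-0	-4.8	-4.3	-2.8	-3	-2.8	-0	-2.7	-3.4	-4.5	-6.4	-5.3
S	-0.8	-1.3	-2.7	-2.7	-2.8	-0.3	-0.8	-2.1	-2.7	-2.1	-1.6	-0.1	-0.3	-0.1	-2.7	-0	-0.7	-1.8	-3.7	-2.6
T	-0.1	-0.6	-3.4	-3.4	-2.1	-0.4	-0.1	-1.4	-3.4	-1.4	-0.9	-0.6	-0.4	-0.6	-3.4	-0.7	-0	-1.1	-3	-1.9
V	-1	-0.5	-4.5	-4.5	-1	-1.5	-1	-0.3	-4.5	-0.3	-0.2	-1.7	-1.5	-1.7	-4.5	-1.8	-1.1	-0	-1.9	-0.8
W	-2.9	-2.4	-6.4	-6.4	-0.9	-3.4	-2.9	-1.6	-6.4	-1.6	-2.1	-3.6	-3.4	-3.6	-6.4	-3.7	-3	-1.9	-0	-1.1
Y	-1.8	-1.3	-5.3	-5.3	-0.2	-2.3	-1.8	-0.5	-5.3	-0.5	-1	-2.5	-2.3	-2.5	-5.3	-2.6	-1.9	-0.8	-1.1	-0
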