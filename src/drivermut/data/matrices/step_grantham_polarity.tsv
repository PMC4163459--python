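wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-2.6	-4.9	-4.2	-2.9	-0.9	-2.3	-2.9	-3.2	-3.2	-2.4	-3.5	-0.1	-2.4	-2.4	-1.1	-0.5	-2.2	-2.7	-1.9
C	-2.6	-0	-7.5	-6.8	-0.3	-3.5	-4.9	-0.3	-5.8	-0.6	-0.2	-6.1	-2.5	-5	-5	-3.7	-3.1	-0.4	-0.1	-0.7
D	-4.9	-7.5	-0	-0.7	-7.8	-4	-2.6	-7.8	-1.7	-8.1	-7.3	-1.4	-5	-2.5	-2.5	-3.8	-4.4	-7.1	-7.6	-6.8
E	-4.2	-6.8	-0.7	-0	-7.1	-3.3	-1.9	-7.1	-1	-7.4	-6.6	-0.7	-4.3	-1.8	-1.8	-3.1	-3.7	-6.4	-6.9	-6.1
F	-2.9	-0.3	-7.8	-7.1	-0	-3.8	-5.2	-0	-6.1	-0.3	-0.5	-6.4	-2.8	-5.3	-5.3	-4	-3.4	-0.7	-0.2	-1
G	-0.9	-3.5	-4	-3.3	-3.8	-0	-1.4	-3.8	-2.3	-4.1	-3.3	-2.6	-1	-1.5	-1.5	-0.2	-0.4	-3.1	-3.6	-2.8
H	-2.3	-4.9	-2.6	-1.9	-5.2	-1.4	-0	-5.2	-0.9	-5.5	-4.7	-1.2	-2.4	-0.1	-0.1	-1.2	-1.8	-4.5	-5	-4.2
I	-2.9	-0.3	-7.8	-7.1	-0	-3.8	-5.2	-0	-6.1	-0.3	-0.5	-6.4	-2.8	-5.3	-5.3	-4	-3.4	-0.7	-0.2	-1
K	-3.2	-5.8	-1.7	-1	-6.1	-2.3	-0.9	-6.1	-0	-6.4	-5.6	-0.3	-3.3	-0.8	-0.8	-2.1	-2.7	-5.4	-5.9	-5.1
L	-3.2	-0.6	-8.1	-7.4	-0.3	-4.1	-5.5	-0.3	-6.4	-0	-0.8	-6.7	-3.1	-5.6	-5.6	-4.3	-3.7	-1	-0.5	-1.3
M	-2.4	-0.2	-7.3	-6.6	-0.5	-3.3	-4.7	-0.5	-5.6	-0.8	-0	-5.9	-2.3	-4.8	-4.8	-3.5	-2.9	-0.2	-0.3	-0.5
N	-3.5	-6.1	-1.4	-0.7	-6.4	-2.6	-1.2	-6.4	-0.3	-6.7	-5.9	-0	-3.6	-1.1	-1.1	-2.4	-3	-5.7	-6.2	-5.4
P	-0.1	-2.5	-5	-4.3	-2.8	-1	-2.4	-2.8	-3.3	-3.1	-2.3	-3.6	-0	-2.5	-2.5	-1.2	-0.6	-2.1	-2.6	-1.8
Q	-2.4	-5	-2.5	-1.8	-5.3	-1.5	-0.1	-5.3	-0.8	-5.6	-4.8	-1.1	-2.5	-0	-0	-1.3	-1.9	-4.6	-5.1	-4.3
R	-2.4	-5	-2.5	-1.8	-5.3	-1.5	-0.1	-5.3	-0.8	-5.6	-4.8	-1.1	-2.5	-0	-0	-1.3	-1.9	-4.6	-5.1	-4.3
S	-1.1	-3.7	-3.8	-3.1	-4	-0.2	-1.2	-4	-2.1	-4.3	-3.5	-2.4	-1.2	-1.3	-1.3	-0	-0.6	-3.3	-3.8	-3
T	-0.5	-3.1	-4.4	-3.7	-3.4	-0.4	-1.8	-3.4	-2.7	-3.7	-2.9	-3	-0.6	-1.9	-1.9	-0.6	-0	-2.7	-3.2	-2.4
V	-2.2	-0.4	-7.1	-6.4	-0.7	-3.1	-4.5	-0.7	-5.4	-1	-0.2	-5.7	-2.1	-4.6	-4.6	-3.3	-2.7	-0	-0.5	-0.3
W	-2.7	-0.1	-7.6	-6.9	-0.2	-3.6	-5	-0.2	-5.9	-0.5	-0.3	-6.2	-2.6	-5.1	-5.1	-3.8	-3.2	-0.5	-0	-0.8
Y	-1.9	-0.7	-6.8	-6.1	-1	-2.8	-4.2	-1	-5.1	-1.3	-0.5	-5.4	-1.8	-4.3	-4.3	-3	-2.4	-0.3	-0.8	-0
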