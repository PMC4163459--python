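wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.7	-5.3	-5.3	-1	-2.2	-5	-2.7	-5.7	-2	-0.1	-5.3	-3.4	-5.3	-6.3	-2.6	-2.5	-2.4	-2.7	-3.1
C	-0.7	-0	-6	-6	-0.3	-2.9	-5.7	-2	-6.4	-1.3	-0.6	-6	-4.1	-6	-7	-3.3	-3.2	-1.7	-3.4	-3.8
D	-5.3	-6	-0	-0	-6.3	-3.1	-0.3	-8	-0.4	-7.3	-5.4	-0	-1.9	-0	-1	-2.7	-2.8	-7.7	-2.6	-2.2
E	-5.3	-6	-0	-0	-6.3	-3.1	-0.3	-8	-0.4	-7.3	-5.4	-0	-1.9	-0	-1	-2.7	-2.8	-7.7	-2.6	-2.2
F	-1	-0.3	-6.3	-6.3	-0	-3.2	-6	-1.7	-6.7	-1	-0.9	-6.3	-4.4	-6.3	-7.3	-3.6	-3.5	-1.4	-3.7	-4.1
G	-2.2	-2.9	-3.1	-3.1	-3.2	-0	-2.8	-4.9	-3.5	-4.2	-2.3	-3.1	-1.2	-3.1	-4.1	-0.4	-0.3	-4.6	-0.5	-0.9
H	-5	-5.7	-0.3	-0.3	-6	-2.8	-0	-7.7	-0.7	-7	-5.1	-0.3	-1.6	-0.3	-1.3	-2.4	-2.5	-7.4	-2.3	-1.9
I	-2.7	-2	-8	-8	-1.7	-4.9	-7.7	-0	-8.4	-0.7	-2.6	-8	-6.1	-8	-9	-5.3	-5.2	-0.3	-5.4	-5.8
K	-5.7	-6.4	-0.4	-0.4	-6.7	-3.5	-0.7	-8.4	-0	-7.7	-5.8	-0.4	-2.3	-0.4	-0.6	-3.1	-3.2	-8.1	-3	-2.6
L	-2	-1.3	-7.3	-7.3	-1	-4.2	-7	-0.7	-7.7	-0	-1.9	-7.3	-5.4	-7.3	-8.3	-4.6	-4.5	-0.4	-4.7	-5.1
M	-0.1	-0.6	-5.4	-5.4	-0.9	-2.3	-5.1	-2.6	-5.8	-1.9	-0	-5.4	-3.5	-5.4	-6.4	-2.7	-2.6	-2.3	-2.8	-3.2
N	-5.3	-6	-0	-0	-6.3	-3.1	-0.3	-8	-0.4	-7.3	-5.4	-0	-1.9	-0	-1	-2.7	-2.8	-7.7	-2.6	-2.2
P	-3.4	-4.1	-1.9	-1.9	-4.4	-1.2	-1.6	-6.1	-2.3	-5.4	-3.5	-1.9	-0	-1.9	-2.9	-0.8	-0.9	-5.8	-0.7	-0.3
Q	-5.3	-6	-0	-0	-6.3	-3.1	-0.3	-8	-0.4	-7.3	-5.4	-0	-1.9	-0	-1	-2.7	-2.8	-7.7	-2.6	-2.2
R	-6.3	-7	-1	-1	-7.3	-4.1	-1.3	-9	-0.6	-8.3	-6.4	-1	-2.9	-1	-0	-3.7	-3.8	-8.7	-3.6	-3.2
S	-2.6	-3.3	-2.7	-2.7	-3.6	-0.4	-2.4	-5.3	-3.1	-4.6	-2.7	-2.7	-0.8	-2.7	-3.7	-0	-0.1	-5	-0.1	-0.5
T	-2.5	-3.2	-2.8	-2.8	-3.5	-0.3	-2.5	-5.2	-3.2	-4.5	-2.6	-2.8	-0.9	-2.8	-3.8	-0.1	-0	-4.9	-0.2	-0.6
V	-2.4	-1.7	-7.7	-7.7	-1.4	-4.6	-7.4	-0.3	-8.1	-0.4	-2.3	-7.7	-5.8	-7.7	-8.7	-5	-4.9	-0	-5.1	-5.5
W	-2.7	-3.4	-2.6	-2.6	-3.7	-0.5	-2.3	-5.4	-3	-4.7	-2.8	-2.6	-0.7	-2.6	-3.6	-0.1	-0.2	-5.1	-0	-0.4
Y	-3.1	-3.8	-2.2	-2.2	-4.1	-0.9	-1.9	-5.8	-2.6	-5.1	-3.2	-2.2	-0.3	-2.2	-3.2	-0.5	-0.6	-5.5	-0.4	-0
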