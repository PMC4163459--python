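wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.4	-10.8	-9.8	-2.1	-0.6	-4.6	-1.5	-10.4	-1.2	-1.8	-6.4	-1.8	-5.7	-13.9	-1	-0.4	-1	-0.3	-2.3
C	-0.4	-0	-11.2	-10.2	-1.7	-1	-5	-1.1	-10.8	-0.8	-1.4	-6.8	-2.2	-6.1	-14.3	-1.4	-0.8	-0.6	-0.1	-2.7
D	-10.8	-11.2	-0	-1	-12.9	-10.2	-6.2	-12.3	-0.4	-12	-12.6	-4.4	-9	-5.1	-3.1	-9.8	-10.4	-11.8	-11.1	-8.5
E	-9.8	-10.2	-1	-0	-11.9	-9.2	-5.2	-11.3	-0.6	-11	-11.6	-3.4	-8	-4.1	-4.1	-8.8	-9.4	-10.8	-10.1	-7.5
F	-2.1	-1.7	-12.9	-11.9	-0	-2.7	-6.7	-0.6	-12.5	-0.9	-0.3	-8.5	-3.9	-7.8	-16	-3.1	-2.5	-1.1	-1.8	-4.4
G	-0.6	-1	-10.2	-9.2	-2.7	-0	-4	-2.1	-9.8	-1.8	-2.4	-5.8	-1.2	-5.1	-13.3	-0.4	-0.2	-1.6	-0.9	-1.7
H	-4.6	-5	-6.2	-5.2	-6.7	-4	-0	-6.1	-5.8	-5.8	-6.4	-1.8	-2.8	-1.1	-9.3	-3.6	-4.2	-5.6	-4.9	-2.3
I	-1.5	-1.1	-12.3	-11.3	-0.6	-2.1	-6.1	-0	-11.9	-0.3	-0.3	-7.9	-3.3	-7.2	-15.4	-2.5	-1.9	-0.5	-1.2	-3.8
K	-10.4	-10.8	-0.4	-0.6	-12.5	-9.8	-5.8	-11.9	-0	-11.6	-12.2	-4	-8.6	-4.7	-3.5	-9.4	-10	-11.4	-10.7	-8.1
L	-1.2	-0.8	-12	-11	-0.9	-1.8	-5.8	-0.3	-11.6	-0	-0.6	-7.6	-3	-6.9	-15.1	-2.2	-1.6	-0.2	-0.9	-3.5
M	-1.8	-1.4	-12.6	-11.6	-0.3	-2.4	-6.4	-0.3	-12.2	-0.6	-0	-8.2	-3.6	-7.5	-15.7	-2.8	-2.2	-0.8	-1.5	-4.1
N	-6.4	-6.8	-4.4	-3.4	-8.5	-5.8	-1.8	-7.9	-4	-7.6	-8.2	-0	-4.6	-0.7	-7.5	-5.4	-6	-7.4	-6.7	-4.1
P	-1.8	-2.2	-9	-8	-3.9	-1.2	-2.8	-3.3	-8.6	-3	-3.6	-4.6	-0	-3.9	-12.1	-0.8	-1.4	-2.8	-2.1	-0.5
Q	-5.7	-6.1	-5.1	-4.1	-7.8	-5.1	-1.1	-7.2	-4.7	-6.9	-7.5	-0.7	-3.9	-0	-8.2	-4.7	-5.3	-6.7	-6	-3.4
R	-13.9	-14.3	-3.1	-4.1	-16	-13.3	-9.3	-15.4	-3.5	-15.1	-15.7	-7.5	-12.1	-8.2	-0	-12.9	-13.5	-14.9	-14.2	-11.6
S	-1	-1.4	-9.8	-8.8	-3.1	-0.4	-3.6	-2.5	-9.4	-2.2	-2.8	-5.4	-0.8	-4.7	-12.9	-0	-0.6	-2	-1.3	-1.3
T	-0.4	-0.8	-10.4	-9.4	-2.5	-0.2	-4.2	-1.9	-10	-1.6	-2.2	-6	-1.4	-5.3	-13.5	-0.6	-0	-1.4	-0.7	-1.9
V	-1	-0.6	-11.8	-10.8	-1.1	-1.6	-5.6	-0.5	-11.4	-0.2	-0.8	-7.4	-2.8	-6.7	-14.9	-2	-1.4	-0	-0.7	-3.3
W	-0.3	-0.1	-11.1	-10.1	-1.8	-0.9	-4.9	-1.2	-10.7	-0.9	-1.5	-6.7	-2.1	-6	-14.2	-1.3	-0.7	-0.7	-0	-2.6
Y	-2.3	-2.7	-8.5	-7.5	-4.4	-1.7	-2.3	-3.8	-8.1	-3.5	-4.1	-4.1	-0.5	-3.4	-11.6	-1.3	-1.9	-3.3	-2.6	-0
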