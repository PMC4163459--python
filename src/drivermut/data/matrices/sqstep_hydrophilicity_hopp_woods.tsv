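wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.25	-12.25	-12.25	-4	-0.25	-0	-1.69	-12.25	-1.69	-0.64	-0.49	-0.25	-0.49	-12.25	-0.64	-0.01	-1	-8.41	-3.24
C	-0.25	-0	-16	-16	-2.25	-1	-0.25	-0.64	-16	-0.64	-0.09	-1.44	-1	-1.44	-16	-1.69	-0.36	-0.25	-5.76	-1.69
D	-12.25	-16	-0	-0	-30.25	-9	-12.25	-23.04	-0	-23.04	-18.49	-7.84	-9	-7.84	-0	-7.29	-11.56	-20.25	-40.96	-28.09
E	-12.25	-16	-0	-0	-30.25	-9	-12.25	-23.04	-0	-23.04	-18.49	-7.84	-9	-7.84	-0	-7.29	-11.56	-20.25	-40.96	-28.09
F	-4	-2.25	-30.25	-30.25	-0	-6.25	-4	-0.49	-30.25	-0.49	-1.44	-7.29	-6.25	-7.29	-30.25	-7.84	-4.41	-1	-0.81	-0.04
G	-0.25	-1	-9	-9	-6.25	-0	-0.25	-3.24	-9	-3.24	-1.69	-0.04	-0	-0.04	-9	-0.09	-0.16	-2.25	-11.56	-5.29
H	-0	-0.25	-12.25	-12.25	-4	-0.25	-0	-1.69	-12.25	-1.69	-0.64	-0.49	-0.25	-0.49	-12.25	-0.64	-0.01	-1	-8.41	-3.24
I	-1.69	-0.64	-23.04	-23.04	-0.49	-3.24	-1.69	-0	-23.04	-0	-0.25	-4	-3.24	-4	-23.04	-4.41	-1.96	-0.09	-2.56	-0.25
K	-12.25	-16	-0	-0	-30.25	-9	-12.25	-23.04	-0	-23.04	-18.49	-7.84	-9	-7.84	-0	-7.29	-11.56	-20.25	-40.96	-28.09
L	-1.69	-0.64	-23.04	-23.04	-0.49	-3.24	-1.69	-0	-23.04	-0	-0.25	-4	-3.24	-4	-23.04	-4.41	-1.96	-0.09	-2.56	-0.25
M	-0.64	-0.09	-18.49	-18.49	-1.44	-1.69	-0.64	-0.25	-18.49	-0.25	-0	-2.25	-1.69	-2.25	-18.49	-2.56	-0.81	-0.04	-4.41	-1
N	-0.49	-1.44	-7.84	-7.84	-7.29	-0.04	-0.49	-4	-7.84	-4	-2.25	-0	-0.04	-0	-7.84	-0.01	-0.36	-2.89	-12.96	-6.25
P	-0.25	-1	-9	-9	-6.25	-0	-0.25	-3.24	-9	-3.24	-1.69	-0.04	-0	-0.04	-9	-0.09	-0.16	-2.25	-11.56	-5.29
Q	-0.49	-1.44	-7.84	-7.84	-7.29	-0.04	-0.49	-4	-7.84	-4	-2.25	-0	-0.04	-0	-7.84	-0.01	-0.36	-2.89	-12.96	-6.25
R	-12.25	-16	-0	-0	-30.25	-9	-12.25	-23.04	-0	-23.04	-18.49	-7.84	-9	-7.84	-0	-7.29	-11.56	-20.25	-40.96	-28.09
S	-0.64	-1.69	-7.29	-7.29	-7.84	-0.09	-0.64	-4.41	-7.29	-4.41	-2.56	-0.01	-0.09	-0.01	-7.29	-0	-0.49	-3.24	-13.69	-6.76
T	-0.01	-0.36	-11.56	-11.56	-4.41	-0.16	-0.01	-1.96	-11.56	-1.96	-0.81	-0.36	-0.16	-0.36	-11.56	-0.49	-0	-1.21	-9	-3.61
V	-1	-0.25	-20.25	-20.25	-1	-2.25	-1	-0.09	-20.25	-0.09	-0.04	-2.89	-2.25	-2.89	-20.25	-3.24	-1.21	-0	-3.61	-0.64
W	-8.41	-5.76	-40.96	-40.96	-0.81	-11.56	-8.41	-2.56	-40.96	-2.56	-4.41	-12.96	-11.56	-12.96	-40.96	-13.69	-9	-3.61	-0	-1.21
Y	-3.24	-1.69	-28.09	-28.09	-0.04	-5.29	-3.24	-0.25	-28.09	-0.25	-1	-6.25	-5.29	-6.25	-28.09	-6.76	-3.61	-0.64	-1.21	-0
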