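wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.49	-28.09	-28.09	-1	-4.84	-25	-7.29	-32.49	-4	-0.01	-28.09	-11.56	-28.09	-39.69	-6.76	-6.25	-5.76	-7.29	-9.61
C	-0.49	-0	-36	-36	-0.09	-8.41	-32.49	-4	-40.96	-1.69	-0.36	-36	-16.81	-36	-49	-10.89	-10.24	-2.89	-11.56	-14.44
D	-28.09	-36	-0	-0	-39.69	-9.61	-0.09	-64	-0.16	-53.29	-29.16	-0	-3.61	-0	-1	-7.29	-7.84	-59.29	-6.76	-4.84
E	-28.09	-36	-0	-0	-39.69	-9.61	-0.09	-64	-0.16	-53.29	-29.16	-0	-3.61	-0	-1	-7.29	-7.84	-59.29	-6.76	-4.84
F	-1	-0.09	-39.69	-39.69	-0	-10.24	-36	-2.89	-44.89	-1	-0.81	-39.69	-19.36	-39.69	-53.29	-12.96	-12.25	-1.96	-13.69	-16.81
G	-4.84	-8.41	-9.61	-9.61	-10.24	-0	-7.84	-24.01	-12.25	-17.64	-5.29	-9.61	-1.44	-9.61	-16.81	-0.16	-0.09	-21.16	-0.25	-0.81
H	-25	-32.49	-0.09	-0.09	-36	-7.84	-0	-59.29	-0.49	-49	-26.01	-0.09	-2.56	-0.09	-1.69	-5.76	-6.25	-54.76	-5.29	-3.61
I	-7.29	-4	-64	-64	-2.89	-24.01	-59.29	-0	-70.56	-0.49	-6.76	-64	-37.21	-64	-81	-28.09	-27.04	-0.09	-29.16	-33.64
K	-32.49	-40.96	-0.16	-0.16	-44.89	-12.25	-0.49	-70.56	-0	-59.29	-33.64	-0.16	-5.29	-0.16	-0.36	-9.61	-10.24	-65.61	-9	-6.76
L	-4	-1.69	-53.29	-53.29	-1	-17.64	-49	-0.49	-59.29	-0	-3.61	-53.29	-29.16	-53.29	-68.89	-21.16	-20.25	-0.16	-22.09	-26.01
M	-0.01	-0.36	-29.16	-29.16	-0.81	-5.29	-26.01	-6.76	-33.64	-3.61	-0	-29.16	-12.25	-29.16	-40.96	-7.29	-6.76	-5.29	-7.84	-10.24
N	-28.09	-36	-0	-0	-39.69	-9.61	-0.09	-64	-0.16	-53.29	-29.16	-0	-3.61	-0	-1	-7.29	-7.84	-59.29	-6.76	-4.84
P	-11.56	-16.81	-3.61	-3.61	-19.36	-1.44	-2.56	-37.21	-5.29	-29.16	-12.25	-3.61	-0	-3.61	-8.41	-0.64	-0.81	-33.64	-0.49	-0.09
Q	-28.09	-36	-0	-0	-39.69	-9.61	-0.09	-64	-0.16	-53.29	-29.16	-0	-3.61	-0	-1	-7.29	-7.84	-59.29	-6.76	-4.84
R	-39.69	-49	-1	-1	-53.29	-16.81	-1.69	-81	-0.36	-68.89	-40.96	-1	-8.41	-1	-0	-13.69	-14.44	-75.69	-12.96	-10.24
S	-6.76	-10.89	-7.29	-7.29	-12.96	-0.16	-5.76	-28.09	-9.61	-21.16	-7.29	-7.29	-0.64	-7.29	-13.69	-0	-0.01	-25	-0.01	-0.25
T	-6.25	-10.24	-7.84	-7.84	-12.25	-0.09	-6.25	-27.04	-10.24	-20.25	-6.76	-7.84	-0.81	-7.84	-14.44	-0.01	-0	-24.01	-0.04	-0.36
V	-5.76	-2.89	-59.29	-59.29	-1.96	-21.16	-54.76	-0.09	-65.61	-0.16	-5.29	-59.29	-33.64	-59.29	-75.69	-25	-24.01	-0	-26.01	-30.25
W	-7.29	-11.56	-6.76	-6.76	-13.69	-0.25	-5.29	-29.16	-9	-22.09	-7.84	-6.76	-0.49	-6.76	-12.96	-0.01	-0.04	-26.01	-0	-0.16
Y	-9.61	-14.44	-4.84	-4.84	-16.81	-0.81	-3.61	-33.64	-6.76	-26.01	-10.24	-4.84	-0.09	-4.84	-10.24	-0.25	-0.36	-30.25	-0.16	-0
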