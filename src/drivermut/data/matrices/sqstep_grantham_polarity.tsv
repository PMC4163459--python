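wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-6.76	-24.01	-17.64	-8.41	-0.81	-5.29	-8.41	-10.24	-10.24	-5.76	-12.25	-0.01	-5.76	-5.76	-1.21	-0.25	-4.84	-7.29	-3.61
C	-6.76	-0	-56.25	-46.24	-0.09	-12.25	-24.01	-0.09	-33.64	-0.36	-0.04	-37.21	-6.25	-25	-25	-13.69	-9.61	-0.16	-0.01	-0.49
D	-24.01	-56.25	-0	-0.49	-60.84	-16	-6.76	-60.84	-2.89	-65.61	-53.29	-1.96	-25	-6.25	-6.25	-14.44	-19.36	-50.41	-57.76	-46.24
E	-17.64	-46.24	-0.49	-0	-50.41	-10.89	-3.61	-50.41	-1	-54.76	-43.56	-0.49	-18.49	-3.24	-3.24	-9.61	-13.69	-40.96	-47.61	-37.21
F	-8.41	-0.09	-60.84	-50.41	-0	-14.44	-27.04	-0	-37.21	-0.09	-0.25	-40.96	-7.84	-28.09	-28.09	-16	-11.56	-0.49	-0.04	-1
G	-0.81	-12.25	-16	-10.89	-14.44	-0	-1.96	-14.44	-5.29	-16.81	-10.89	-6.76	-1	-2.25	-2.25	-0.04	-0.16	-9.61	-12.96	-7.84
H	-5.29	-24.01	-6.76	-3.61	-27.04	-1.96	-0	-27.04	-0.81	-30.25	-22.09	-1.44	-5.76	-0.01	-0.01	-1.44	-3.24	-20.25	-25	-17.64
I	-8.41	-0.09	-60.84	-50.41	-0	-14.44	-27.04	-0	-37.21	-0.09	-0.25	-40.96	-7.84	-28.09	-28.09	-16	-11.56	-0.49	-0.04	-1
K	-10.24	-33.64	-2.89	-1	-37.21	-5.29	-0.81	-37.21	-0	-40.96	-31.36	-0.09	-10.89	-0.64	-0.64	-4.41	-7.29	-29.16	-34.81	-26.01
L	-10.24	-0.36	-65.61	-54.76	-0.09	-16.81	-30.25	-0.09	-40.96	-0	-0.64	-44.89	-9.61	-31.36	-31.36	-18.49	-13.69	-1	-0.25	-1.69
M	-5.76	-0.04	-53.29	-43.56	-0.25	-10.89	-22.09	-0.25	-31.36	-0.64	-0	-34.81	-5.29	-23.04	-23.04	-12.25	-8.41	-0.04	-0.09	-0.25
N	-12.25	-37.21	-1.96	-0.49	-40.96	-6.76	-1.44	-40.96	-0.09	-44.89	-34.81	-0	-12.96	-1.21	-1.21	-5.76	-9	-32.49	-38.44	-29.16
P	-0.01	-6.25	-25	-18.49	-7.84	-1	-5.76	-7.84	-10.89	-9.61	-5.29	-12.96	-0	-6.25	-6.25	-1.44	-0.36	-4.41	-6.76	-3.24
Q	-5.76	-25	-6.25	-3.24	-28.09	-2.25	-0.01	-28.09	-0.64	-31.36	-23.04	-1.21	-6.25	-0	-0	-1.69	-3.61	-21.16	-26.01	-18.49
R	-5.76	-25	-6.25	-3.24	-28.09	-2.25	-0.01	-28.09	-0.64	-31.36	-23.04	-1.21	-6.25	-0	-0	-1.69	-3.61	-21.16	-26.01	-18.49
S	-1.21	-13.69	-14.44	-9.61	-16	-0.04	-1.44	-16	-4.41	-18.49	-12.25	-5.76	-1.44	-1.69	-1.69	-0	-0.36	-10.89	-14.44	-9
T	-0.25	-9.61	-19.36	-13.69	-11.56	-0.16	-3.24	-11.56	-7.29	-13.69	-8.41	-9	-0.36	-3.61	-3.61	-0.36	-0	-7.29	-10.24	-5.76
V	-4.84	-0.16	-50.41	-40.96	-0.49	-9.61	-20.25	-0.49	-29.16	-1	-0.04	-32.49	-4.41	-21.16	-21.16	-10.89	-7.29	-0	-0.25	-0.09
W	-7.29	-0.01	-57.76	-47.61	-0.04	-12.96	-25	-0.04	-34.81	-0.25	-0.09	-38.44	-6.76	-26.01	-26.01	-14.44	-10.24	-0.25	-0	-0.64
Y	-3.61	-0.49	-46.24	-37.21	-1	-7.84	-17.64	-1	-26.01	-1.69	-0.25	-29.16	-3.24	-18.49	-18.49	-9	-5.76	-0.09	-0.64	-0
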