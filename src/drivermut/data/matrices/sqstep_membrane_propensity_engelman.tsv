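wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.16	-116.64	-96.04	-4.41	-0.36	-21.16	-2.25	-108.16	-1.44	-3.24	-40.96	-3.24	-32.49	-193.21	-1	-0.16	-1	-0.09	-5.29
C	-0.16	-0	-125.44	-104.04	-2.89	-1	-25	-1.21	-116.64	-0.64	-1.96	-46.24	-4.84	-37.21	-204.49	-1.96	-0.64	-0.36	-0.01	-7.29
D	-116.64	-125.44	-0	-1	-166.41	-104.04	-38.44	-151.29	-0.16	-144	-158.76	-19.36	-81	-26.01	-9.61	-96.04	-108.16	-139.24	-123.21	-72.25
E	-96.04	-104.04	-1	-0	-141.61	-84.64	-27.04	-127.69	-0.36	-121	-134.56	-11.56	-64	-16.81	-16.81	-77.44	-88.36	-116.64	-102.01	-56.25
F	-4.41	-2.89	-166.41	-141.61	-0	-7.29	-44.89	-0.36	-156.25	-0.81	-0.09	-72.25	-15.21	-60.84	-256	-9.61	-6.25	-1.21	-3.24	-19.36
G	-0.36	-1	-104.04	-84.64	-7.29	-0	-16	-4.41	-96.04	-3.24	-5.76	-33.64	-1.44	-26.01	-176.89	-0.16	-0.04	-2.56	-0.81	-2.89
H	-21.16	-25	-38.44	-27.04	-44.89	-16	-0	-37.21	-33.64	-33.64	-40.96	-3.24	-7.84	-1.21	-86.49	-12.96	-17.64	-31.36	-24.01	-5.29
I	-2.25	-1.21	-151.29	-127.69	-0.36	-4.41	-37.21	-0	-141.61	-0.09	-0.09	-62.41	-10.89	-51.84	-237.16	-6.25	-3.61	-0.25	-1.44	-14.44
K	-108.16	-116.64	-0.16	-0.36	-156.25	-96.04	-33.64	-141.61	-0	-134.56	-148.84	-16	-73.96	-22.09	-12.25	-88.36	-100	-129.96	-114.49	-65.61
L	-1.44	-0.64	-144	-121	-0.81	-3.24	-33.64	-0.09	-134.56	-0	-0.36	-57.76	-9	-47.61	-228.01	-4.84	-2.56	-0.04	-0.81	-12.25
M	-3.24	-1.96	-158.76	-134.56	-0.09	-5.76	-40.96	-0.09	-148.84	-0.36	-0	-67.24	-12.96	-56.25	-246.49	-7.84	-4.84	-0.64	-2.25	-16.81
N	-40.96	-46.24	-19.36	-11.56	-72.25	-33.64	-3.24	-62.41	-16	-57.76	-67.24	-0	-21.16	-0.49	-56.25	-29.16	-36	-54.76	-44.89	-16.81
P	-3.24	-4.84	-81	-64	-15.21	-1.44	-7.84	-10.89	-73.96	-9	-12.96	-21.16	-0	-15.21	-146.41	-0.64	-1.96	-7.84	-4.41	-0.25
Q	-32.49	-37.21	-26.01	-16.81	-60.84	-26.01	-1.21	-51.84	-22.09	-47.61	-56.25	-0.49	-15.21	-0	-67.24	-22.09	-28.09	-44.89	-36	-11.56
R	-193.21	-204.49	-9.61	-16.81	-256	-176.89	-86.49	-237.16	-12.25	-228.01	-246.49	-56.25	-146.41	-67.24	-0	-166.41	-182.25	-222.01	-201.64	-134.56
S	-1	-1.96	-96.04	-77.44	-9.61	-0.16	-12.96	-6.25	-88.36	-4.84	-7.84	-29.16	-0.64	-22.09	-166.41	-0	-0.36	-4	-1.69	-1.69
T	-0.16	-0.64	-108.16	-88.36	-6.25	-0.04	-17.64	-3.61	-100	-2.56	-4.84	-36	-1.96	-28.09	-182.25	-0.36	-0	-1.96	-0.49	-3.61
V	-1	-0.36	-139.24	-116.64	-1.21	-2.56	-31.36	-0.25	-129.96	-0.04	-0.64	-54.76	-7.84	-44.89	-222.01	-4	-1.96	-0	-0.49	-10.89
W	-0.09	-0.01	-123.21	-102.01	-3.24	-0.81	-24.01	-1.44	-114.49	-0.81	-2.25	-44.89	-4.41	-36	-201.64	-1.69	-0.49	-0.49	-0	-6.76
Y	-5.29	-7.29	-72.25	-56.25	-19.36	-2.89	-5.29	-14.44	-65.61	-12.25	-16.81	-16.81	-0.25	-11.56	-134.56	-1.69	-3.61	-10.89	-6.76	-0
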