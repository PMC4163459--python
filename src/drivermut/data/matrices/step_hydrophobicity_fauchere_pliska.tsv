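wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-1.23	-1.08	-0.95	-1.48	-0.31	-0.18	-1.49	-1.3	-1.39	-0.92	-0.91	-0.41	-0.53	-1.32	-0.35	-0.05	-0.91	-1.94	-0.65
C	-1.23	-0	-2.31	-2.18	-0.25	-1.54	-1.41	-0.26	-2.53	-0.16	-0.31	-2.14	-0.82	-1.76	-2.55	-1.58	-1.28	-0.32	-0.71	-0.58
D	-1.08	-2.31	-0	-0.13	-2.56	-0.77	-0.9	-2.57	-0.22	-2.47	-2	-0.17	-1.49	-0.55	-0.24	-0.73	-1.03	-1.99	-3.02	-1.73
E	-0.95	-2.18	-0.13	-0	-2.43	-0.64	-0.77	-2.44	-0.35	-2.34	-1.87	-0.04	-1.36	-0.42	-0.37	-0.6	-0.9	-1.86	-2.89	-1.6
F	-1.48	-0.25	-2.56	-2.43	-0	-1.79	-1.66	-0.01	-2.78	-0.09	-0.56	-2.39	-1.07	-2.01	-2.8	-1.83	-1.53	-0.57	-0.46	-0.83
G	-0.31	-1.54	-0.77	-0.64	-1.79	-0	-0.13	-1.8	-0.99	-1.7	-1.23	-0.6	-0.72	-0.22	-1.01	-0.04	-0.26	-1.22	-2.25	-0.96
H	-0.18	-1.41	-0.9	-0.77	-1.66	-0.13	-0	-1.67	-1.12	-1.57	-1.1	-0.73	-0.59	-0.35	-1.14	-0.17	-0.13	-1.09	-2.12	-0.83
I	-1.49	-0.26	-2.57	-2.44	-0.01	-1.8	-1.67	-0	-2.79	-0.1	-0.57	-2.4	-1.08	-2.02	-2.81	-1.84	-1.54	-0.58	-0.45	-0.84
K	-1.3	-2.53	-0.22	-0.35	-2.78	-0.99	-1.12	-2.79	-0	-2.69	-2.22	-0.39	-1.71	-0.77	-0.02	-0.95	-1.25	-2.21	-3.24	-1.95
L	-1.39	-0.16	-2.47	-2.34	-0.09	-1.7	-1.57	-0.1	-2.69	-0	-0.47	-2.3	-0.98	-1.92	-2.71	-1.74	-1.44	-0.48	-0.55	-0.74
M	-0.92	-0.31	-2	-1.87	-0.56	-1.23	-1.1	-0.57	-2.22	-0.47	-0	-1.83	-0.51	-1.45	-2.24	-1.27	-0.97	-0.01	-1.02	-0.27
N	-0.91	-2.14	-0.17	-0.04	-2.39	-0.6	-0.73	-2.4	-0.39	-2.3	-1.83	-0	-1.32	-0.38	-0.41	-0.56	-0.86	-1.82	-2.85	-1.56
P	-0.41	-0.82	-1.49	-1.36	-1.07	-0.72	-0.59	-1.08	-1.71	-0.98	-0.51	-1.32	-0	-0.94	-1.73	-0.76	-0.46	-0.5	-1.53	-0.24
Q	-0.53	-1.76	-0.55	-0.42	-2.01	-0.22	-0.35	-2.02	-0.77	-1.92	-1.45	-0.38	-0.94	-0	-0.79	-0.18	-0.48	-1.44	-2.47	-1.18
R	-1.32	-2.55	-0.24	-0.37	-2.8	-1.01	-1.14	-2.81	-0.02	-2.71	-2.24	-0.41	-1.73	-0.79	-0	-0.97	-1.27	-2.23	-3.26	-1.97
S	-0.35	-1.58	-0.73	-0.6	-1.83	-0.04	-0.17	-1.84	-0.95	-1.74	-1.27	-0.56	-0.76	-0.18	-0.97	-0	-0.3	-1.26	-2.29	-1
T	-0.05	-1.28	-1.03	-0.9	-1.53	-0.26	-0.13	-1.54	-1.25	-1.44	-0.97	-0.86	-0.46	-0.48	-1.27	-0.3	-0	-0.96	-1.99	-0.7
V	-0.91	-0.32	-1.99	-1.86	-0.57	-1.22	-1.09	-0.58	-2.21	-0.48	-0.01	-1.82	-0.5	-1.44	-2.23	-1.26	-0.96	-0	-1.03	-0.26
W	-1.94	-0.71	-3.02	-2.89	-0.46	-2.25	-2.12	-0.45	-3.24	-0.55	-1.02	-2.85	-1.53	-2.47	-3.26	-2.29	-1.99	-1.03	-0	-1.29
Y	-0.65	-0.58	-1.73	-1.6	-0.83	-0.96	-0.83	-0.84	-1.95	-0.74	-0.27	-1.56	-0.24	-1.18	-1.97	-1	-0.7	-0.26	-1.29	-0
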