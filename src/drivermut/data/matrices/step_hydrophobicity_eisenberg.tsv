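wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.33	-1.52	-1.36	-0.57	-0.14	-1.02	-0.76	-2.12	-0.44	-0.02	-1.4	-0.5	-1.47	-3.15	-0.8	-0.67	-0.46	-0.19	-0.36
C	-0.33	-0	-1.19	-1.03	-0.9	-0.19	-0.69	-1.09	-1.79	-0.77	-0.35	-1.07	-0.17	-1.14	-2.82	-0.47	-0.34	-0.79	-0.52	-0.03
D	-1.52	-1.19	-0	-0.16	-2.09	-1.38	-0.5	-2.28	-0.6	-1.96	-1.54	-0.12	-1.02	-0.05	-1.63	-0.72	-0.85	-1.98	-1.71	-1.16
E	-1.36	-1.03	-0.16	-0	-1.93	-1.22	-0.34	-2.12	-0.76	-1.8	-1.38	-0.04	-0.86	-0.11	-1.79	-0.56	-0.69	-1.82	-1.55	-1
F	-0.57	-0.9	-2.09	-1.93	-0	-0.71	-1.59	-0.19	-2.69	-0.13	-0.55	-1.97	-1.07	-2.04	-3.72	-1.37	-1.24	-0.11	-0.38	-0.93
G	-0.14	-0.19	-1.38	-1.22	-0.71	-0	-0.88	-0.9	-1.98	-0.58	-0.16	-1.26	-0.36	-1.33	-3.01	-0.66	-0.53	-0.6	-0.33	-0.22
H	-1.02	-0.69	-0.5	-0.34	-1.59	-0.88	-0	-1.78	-1.1	-1.46	-1.04	-0.38	-0.52	-0.45	-2.13	-0.22	-0.35	-1.48	-1.21	-0.66
I	-0.76	-1.09	-2.28	-2.12	-0.19	-0.9	-1.78	-0	-2.88	-0.32	-0.74	-2.16	-1.26	-2.23	-3.91	-1.56	-1.43	-0.3	-0.57	-1.12
K	-2.12	-1.79	-0.6	-0.76	-2.69	-1.98	-1.1	-2.88	-0	-2.56	-2.14	-0.72	-1.62	-0.65	-1.03	-1.32	-1.45	-2.58	-2.31	-1.76
L	-0.44	-0.77	-1.96	-1.8	-0.13	-0.58	-1.46	-0.32	-2.56	-0	-0.42	-1.84	-0.94	-1.91	-3.59	-1.24	-1.11	-0.02	-0.25	-0.8
M	-0.02	-0.35	-1.54	-1.38	-0.55	-0.16	-1.04	-0.74	-2.14	-0.42	-0	-1.42	-0.52	-1.49	-3.17	-0.82	-0.69	-0.44	-0.17	-0.38
N	-1.4	-1.07	-0.12	-0.04	-1.97	-1.26	-0.38	-2.16	-0.72	-1.84	-1.42	-0	-0.9	-0.07	-1.75	-0.6	-0.73	-1.86	-1.59	-1.04
P	-0.5	-0.17	-1.02	-0.86	-1.07	-0.36	-0.52	-1.26	-1.62	-0.94	-0.52	-0.9	-0	-0.97	-2.65	-0.3	-0.17	-0.96	-0.69	-0.14
Q	-1.47	-1.14	-0.05	-0.11	-2.04	-1.33	-0.45	-2.23	-0.65	-1.91	-1.49	-0.07	-0.97	-0	-1.68	-0.67	-0.8	-1.93	-1.66	-1.11
R	-3.15	-2.82	-1.63	-1.79	-3.72	-3.01	-2.13	-3.91	-1.03	-3.59	-3.17	-1.75	-2.65	-1.68	-0	-2.35	-2.48	-3.61	-3.34	-2.79
S	-0.8	-0.47	-0.72	-0.56	-1.37	-0.66	-0.22	-1.56	-1.32	-1.24	-0.82	-0.6	-0.3	-0.67	-2.35	-0	-0.13	-1.26	-0.99	-0.44
T	-0.67	-0.34	-0.85	-0.69	-1.24	-0.53	-0.35	-1.43	-1.45	-1.11	-0.69	-0.73	-0.17	-0.8	-2.48	-0.13	-0	-1.13	-0.86	-0.31
V	-0.46	-0.79	-1.98	-1.82	-0.11	-0.6	-1.48	-0.3	-2.58	-0.02	-0.44	-1.86	-0.96	-1.93	-3.61	-1.26	-1.13	-0	-0.27	-0.82
W	-0.19	-0.52	-1.71	-1.55	-0.38	-0.33	-1.21	-0.57	-2.31	-0.25	-0.17	-1.59	-0.69	-1.66	-3.34	-0.99	-0.86	-0.27	-0	-0.55
Y	-0.36	-0.03	-1.16	-1	-0.93	-0.22	-0.66	-1.12	-1.76	-0.8	-0.38	-1.04	-0.14	-1.11	-2.79	-0.44	-0.31	-0.82	-0.55	-0
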