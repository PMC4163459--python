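wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.33	-0.71	-1.36	-0.57	-0.14	-1.02	-0.76	-2.12	-0.91	-0.02	-1.4	-0.5	-1.47	-3.15	-0.8	-0.67	-1.18	-0.19	-0.36
C	-0.33	-0	-0.38	-1.03	-0.9	-0.19	-0.69	-1.09	-1.79	-1.24	-0.35	-1.07	-0.17	-1.14	-2.82	-0.47	-0.34	-1.51	-0.52	-0.03
D	-0.71	-0.38	-0	-0.65	-1.28	-0.57	-0.31	-1.47	-1.41	-1.62	-0.73	-0.69	-0.21	-0.76	-2.44	-0.09	-0.04	-1.89	-0.9	-0.35
E	-1.36	-1.03	-0.65	-0	-1.93	-1.22	-0.34	-2.12	-0.76	-2.27	-1.38	-0.04	-0.86	-0.11	-1.79	-0.56	-0.69	-2.54	-1.55	-1
F	-0.57	-0.9	-1.28	-1.93	-0	-0.71	-1.59	-0.19	-2.69	-0.34	-0.55	-1.97	-1.07	-2.04	-3.72	-1.37	-1.24	-0.61	-0.38	-0.93
G	-0.14	-0.19	-0.57	-1.22	-0.71	-0	-0.88	-0.9	-1.98	-1.05	-0.16	-1.26	-0.36	-1.33	-3.01	-0.66	-0.53	-1.32	-0.33	-0.22
H	-1.02	-0.69	-0.31	-0.34	-1.59	-0.88	-0	-1.78	-1.1	-1.93	-1.04	-0.38	-0.52	-0.45	-2.13	-0.22	-0.35	-2.2	-1.21	-0.66
I	-0.76	-1.09	-1.47	-2.12	-0.19	-0.9	-1.78	-0	-2.88	-0.15	-0.74	-2.16	-1.26	-2.23	-3.91	-1.56	-1.43	-0.42	-0.57	-1.12
K	-2.12	-1.79	-1.41	-0.76	-2.69	-1.98	-1.1	-2.88	-0	-3.03	-2.14	-0.72	-1.62	-0.65	-1.03	-1.32	-1.45	-3.3	-2.31	-1.76
L	-0.91	-1.24	-1.62	-2.27	-0.34	-1.05	-1.93	-0.15	-3.03	-0	-0.89	-2.31	-1.41	-2.38	-4.06	-1.71	-1.58	-0.27	-0.72	-1.27
M	-0.02	-0.35	-0.73	-1.38	-0.55	-0.16	-1.04	-0.74	-2.14	-0.89	-0	-1.42	-0.52	-1.49	-3.17	-0.82	-0.69	-1.16	-0.17	-0.38
N	-1.4	-1.07	-0.69	-0.04	-1.97	-1.26	-0.38	-2.16	-0.72	-2.31	-1.42	-0	-0.9	-0.07	-1.75	-0.6	-0.73	-2.58	-1.59	-1.04
P	-0.5	-0.17	-0.21	-0.86	-1.07	-0.36	-0.52	-1.26	-1.62	-1.41	-0.52	-0.9	-0	-0.97	-2.65	-0.3	-0.17	-1.68	-0.69	-0.14
Q	-1.47	-1.14	-0.76	-0.11	-2.04	-1.33	-0.45	-2.23	-0.65	-2.38	-1.49	-0.07	-0.97	-0	-1.68	-0.67	-0.8	-2.65	-1.66	-1.11
R	-3.15	-2.82	-2.44	-1.79	-3.72	-3.01	-2.13	-3.91	-1.03	-4.06	-3.17	-1.75	-2.65	-1.68	-0	-2.35	-2.48	-4.33	-3.34	-2.79
S	-0.8	-0.47	-0.09	-0.56	-1.37	-0.66	-0.22	-1.56	-1.32	-1.71	-0.82	-0.6	-0.3	-0.67	-2.35	-0	-0.13	-1.98	-0.99	-0.44
T	-0.67	-0.34	-0.04	-0.69	-1.24	-0.53	-0.35	-1.43	-1.45	-1.58	-0.69	-0.73	-0.17	-0.8	-2.48	-0.13	-0	-1.85	-0.86	-0.31
V	-1.18	-1.51	-1.89	-2.54	-0.61	-1.32	-2.2	-0.42	-3.3	-0.27	-1.16	-2.58	-1.68	-2.65	-4.33	-1.98	-1.85	-0	-0.99	-1.54
W	-0.19	-0.52	-0.9	-1.55	-0.38	-0.33	-1.21	-0.57	-2.31	-0.72	-0.17	-1.59	-0.69	-1.66	-3.34	-0.99	-0.86	-0.99	-0	-0.55
Y	-0.36	-0.03	-0.35	-1	-0.93	-0.22	-0.66	-1.12	-1.76	-1.27	-0.38	-1.04	-0.14	-1.11	-2.79	-0.44	-0.31	-1.54	-0.55	-0
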