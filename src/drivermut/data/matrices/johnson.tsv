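wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.6	-0.34	-0.16	-0.07	-0.32	-0.05	-0.31	-0.22	-0.09	-0.33	-0.15	-0.14	-0.1	-0.06	-0.16	0	-0.08	-0.05	-0.58	-0.4
C	-0.34	1.61	-0.97	-0.69	-0.44	-0.82	-0.82	-0.77	-0.87	-0.87	-0.44	-0.76	-0.89	-0.69	-0.56	-0.77	-0.6	-0.48	-0.91	-0.77
D	-0.16	-0.97	0.85	0.24	-0.7	-0.21	-0.07	-0.48	-0.15	-0.8	-0.59	0.26	-0.1	-0.11	-0.34	-0.02	-0.18	-0.52	-0.6	-0.38
E	-0.07	-0.69	0.24	0.86	-0.64	-0.25	-0.23	-0.48	0.11	-0.56	-0.28	-0.07	-0.15	0.24	-0.02	-0.22	-0.05	-0.42	-0.76	-0.37
F	-0.32	-0.44	-0.7	-0.64	1.04	-0.86	-0.17	0.05	-0.56	0.18	-0.06	-0.38	-0.5	-0.64	-0.6	-0.48	-0.5	-0.13	0.34	0.34
G	-0.05	-0.82	-0.21	-0.25	-0.86	0.8	-0.32	-0.55	-0.35	-0.72	-0.52	-0.14	-0.25	-0.28	-0.28	-0.13	-0.38	-0.56	-0.63	-0.54
H	-0.31	-0.82	-0.07	-0.23	-0.17	-0.32	1.27	-0.51	0.01	-0.42	-0.23	0.17	-0.43	0.14	0.01	-0.26	-0.3	-0.39	-0.4	-0.04
I	-0.22	-0.77	-0.48	-0.48	0.05	-0.55	-0.51	0.81	-0.47	0.26	0.26	-0.47	-0.57	-0.7	-0.54	-0.47	-0.32	0.39	-0.33	-0.25
K	-0.09	-0.87	-0.15	0.11	-0.56	-0.35	0.01	-0.47	0.76	-0.34	-0.19	0.01	-0.06	0.11	0.32	-0.15	-0.02	-0.37	-0.54	-0.37
L	-0.33	-0.87	-0.8	-0.56	0.18	-0.72	-0.42	0.26	-0.34	0.73	0.44	-0.48	-0.28	-0.44	-0.37	-0.52	-0.46	0.18	-0.1	-0.24
M	-0.15	-0.44	-0.59	-0.28	-0.06	-0.52	-0.23	0.26	-0.19	0.44	1.12	-0.37	-0.98	-0.06	-0.42	-0.48	-0.32	0.07	-0.09	-0.13
N	-0.14	-0.76	0.26	-0.07	-0.38	-0.14	0.17	-0.47	0.01	-0.48	-0.37	0.8	-0.24	-0.08	-0.15	0.1	0.01	-0.57	-0.61	-0.13
P	-0.1	-0.89	-0.1	-0.15	-0.5	-0.25	-0.43	-0.57	-0.06	-0.28	-0.98	-0.24	1.03	-0.36	-0.36	-0.1	-0.2	-0.52	-0.74	-0.7
Q	-0.06	-0.69	-0.11	0.24	-0.64	-0.28	0.14	-0.7	0.11	-0.44	-0.06	-0.08	-0.36	0.9	0.21	-0.12	-0.04	-0.36	-0.82	-0.51
R	-0.16	-0.56	-0.34	-0.02	-0.6	-0.28	0.01	-0.54	0.32	-0.37	-0.42	-0.15	-0.36	0.21	1	-0.06	-0.14	-0.49	-0.38	-0.21
S	0	-0.77	-0.02	-0.22	-0.48	-0.13	-0.26	-0.47	-0.15	-0.52	-0.48	0.1	-0.1	-0.12	-0.06	0.58	0.2	-0.43	-0.62	-0.34
T	-0.08	-0.6	-0.18	-0.05	-0.5	-0.38	-0.3	-0.32	-0.02	-0.46	-0.32	0.01	-0.2	-0.04	-0.14	0.2	0.68	-0.19	-0.93	-0.27
V	-0.05	-0.48	-0.52	-0.42	-0.13	-0.56	-0.39	0.39	-0.37	0.18	0.07	-0.57	-0.52	-0.36	-0.49	-0.43	-0.19	0.7	-0.49	-0.18
W	-0.58	-0.91	-0.6	-0.76	0.34	-0.63	-0.4	-0.33	-0.54	-0.1	-0.09	-0.61	-0.74	-0.82	-0.38	-0.62	-0.93	-0.49	1.52	0.23
Y	-0.4	-0.77	-0.38	-0.37	0.34	-0.54	-0.04	-0.25	-0.37	-0.24	-0.13	-0.13	-0.7	-0.51	-0.21	-0.34	-0.27	-0.18	0.23	1.05
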