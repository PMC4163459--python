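wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-2.75	-1.38	-0.92	-0	-0.74	-0.58	-0	-0.33	-0	-0	-1.33	-0.39	-0.89	-0.65	-1.42	-0.71	-0	-0.13	-0.2
C	-2.75	-0	-1.37	-1.83	-2.75	-2.01	-2.17	-2.75	-2.42	-2.75	-2.75	-1.42	-2.36	-1.86	-2.1	-1.33	-2.04	-2.75	-2.62	-2.55
D	-1.38	-1.37	-0	-0.46	-1.38	-0.64	-0.8	-1.38	-1.05	-1.38	-1.38	-0.05	-0.99	-0.49	-0.73	-0.04	-0.67	-1.38	-1.25	-1.18
E	-0.92	-1.83	-0.46	-0	-0.92	-0.18	-0.34	-0.92	-0.59	-0.92	-0.92	-0.41	-0.53	-0.03	-0.27	-0.5	-0.21	-0.92	-0.79	-0.72
F	-0	-2.75	-1.38	-0.92	-0	-0.74	-0.58	-0	-0.33	-0	-0	-1.33	-0.39	-0.89	-0.65	-1.42	-0.71	-0	-0.13	-0.2
G	-0.74	-2.01	-0.64	-0.18	-0.74	-0	-0.16	-0.74	-0.41	-0.74	-0.74	-0.59	-0.35	-0.15	-0.09	-0.68	-0.03	-0.74	-0.61	-0.54
H	-0.58	-2.17	-0.8	-0.34	-0.58	-0.16	-0	-0.58	-0.25	-0.58	-0.58	-0.75	-0.19	-0.31	-0.07	-0.84	-0.13	-0.58	-0.45	-0.38
I	-0	-2.75	-1.38	-0.92	-0	-0.74	-0.58	-0	-0.33	-0	-0	-1.33	-0.39	-0.89	-0.65	-1.42	-0.71	-0	-0.13	-0.2
K	-0.33	-2.42	-1.05	-0.59	-0.33	-0.41	-0.25	-0.33	-0	-0.33	-0.33	-1	-0.06	-0.56	-0.32	-1.09	-0.38	-0.33	-0.2	-0.13
L	-0	-2.75	-1.38	-0.92	-0	-0.74	-0.58	-0	-0.33	-0	-0	-1.33	-0.39	-0.89	-0.65	-1.42	-0.71	-0	-0.13	-0.2
M	-0	-2.75	-1.38	-0.92	-0	-0.74	-0.58	-0	-0.33	-0	-0	-1.33	-0.39	-0.89	-0.65	-1.42	-0.71	-0	-0.13	-0.2
N	-1.33	-1.42	-0.05	-0.41	-1.33	-0.59	-0.75	-1.33	-1	-1.33	-1.33	-0	-0.94	-0.44	-0.68	-0.09	-0.62	-1.33	-1.2	-1.13
P	-0.39	-2.36	-0.99	-0.53	-0.39	-0.35	-0.19	-0.39	-0.06	-0.39	-0.39	-0.94	-0	-0.5	-0.26	-1.03	-0.32	-0.39	-0.26	-0.19
Q	-0.89	-1.86	-0.49	-0.03	-0.89	-0.15	-0.31	-0.89	-0.56	-0.89	-0.89	-0.44	-0.5	-0	-0.24	-0.53	-0.18	-0.89	-0.76	-0.69
R	-0.65	-2.1	-0.73	-0.27	-0.65	-0.09	-0.07	-0.65	-0.32	-0.65	-0.65	-0.68	-0.26	-0.24	-0	-0.77	-0.06	-0.65	-0.52	-0.45
S	-1.42	-1.33	-0.04	-0.5	-1.42	-0.68	-0.84	-1.42	-1.09	-1.42	-1.42	-0.09	-1.03	-0.53	-0.77	-0	-0.71	-1.42	-1.29	-1.22
T	-0.71	-2.04	-0.67	-0.21	-0.71	-0.03	-0.13	-0.71	-0.38	-0.71	-0.71	-0.62	-0.32	-0.18	-0.06	-0.71	-0	-0.71	-0.58	-0.51
V	-0	-2.75	-1.38	-0.92	-0	-0.74	-0.58	-0	-0.33	-0	-0	-1.33	-0.39	-0.89	-0.65	-1.42	-0.71	-0	-0.13	-0.2
W	-0.13	-2.62	-1.25	-0.79	-0.13	-0.61	-0.45	-0.13	-0.2	-0.13	-0.13	-1.2	-0.26	-0.76	-0.52	-1.29	-0.58	-0.13	-0	-0.07
Y	-0.2	-2.55	-1.18	-0.72	-0.2	-0.54	-0.38	-0.2	-0.13	-0.2	-0.2	-1.13	-0.19	-0.69	-0.45	-1.22	-0.51	-0.2	-0.07	-0
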