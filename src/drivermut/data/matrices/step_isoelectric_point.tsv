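wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.93	-3.23	-2.78	-0.52	-0.03	-1.59	-0.02	-3.74	-0.02	-0.26	-0.59	-0.3	-0.35	-4.76	-0.32	-0.4	-0.04	-0.11	-0.34
C	-0.93	-0	-2.3	-1.85	-0.41	-0.9	-2.52	-0.95	-4.67	-0.91	-0.67	-0.34	-1.23	-0.58	-5.69	-0.61	-0.53	-0.89	-0.82	-0.59
D	-3.23	-2.3	-0	-0.45	-2.71	-3.2	-4.82	-3.25	-6.97	-3.21	-2.97	-2.64	-3.53	-2.88	-7.99	-2.91	-2.83	-3.19	-3.12	-2.89
E	-2.78	-1.85	-0.45	-0	-2.26	-2.75	-4.37	-2.8	-6.52	-2.76	-2.52	-2.19	-3.08	-2.43	-7.54	-2.46	-2.38	-2.74	-2.67	-2.44
F	-0.52	-0.41	-2.71	-2.26	-0	-0.49	-2.11	-0.54	-4.26	-0.5	-0.26	-0.07	-0.82	-0.17	-5.28	-0.2	-0.12	-0.48	-0.41	-0.18
G	-0.03	-0.9	-3.2	-2.75	-0.49	-0	-1.62	-0.05	-3.77	-0.01	-0.23	-0.56	-0.33	-0.32	-4.79	-0.29	-0.37	-0.01	-0.08	-0.31
H	-1.59	-2.52	-4.82	-4.37	-2.11	-1.62	-0	-1.57	-2.15	-1.61	-1.85	-2.18	-1.29	-1.94	-3.17	-1.91	-1.99	-1.63	-1.7	-1.93
I	-0.02	-0.95	-3.25	-2.8	-0.54	-0.05	-1.57	-0	-3.72	-0.04	-0.28	-0.61	-0.28	-0.37	-4.74	-0.34	-0.42	-0.06	-0.13	-0.36
K	-3.74	-4.67	-6.97	-6.52	-4.26	-3.77	-2.15	-3.72	-0	-3.76	-4	-4.33	-3.44	-4.09	-1.02	-4.06	-4.14	-3.78	-3.85	-4.08
L	-0.02	-0.91	-3.21	-2.76	-0.5	-0.01	-1.61	-0.04	-3.76	-0	-0.24	-0.57	-0.32	-0.33	-4.78	-0.3	-0.38	-0.02	-0.09	-0.32
M	-0.26	-0.67	-2.97	-2.52	-0.26	-0.23	-1.85	-0.28	-4	-0.24	-0	-0.33	-0.56	-0.09	-5.02	-0.06	-0.14	-0.22	-0.15	-0.08
N	-0.59	-0.34	-2.64	-2.19	-0.07	-0.56	-2.18	-0.61	-4.33	-0.57	-0.33	-0	-0.89	-0.24	-5.35	-0.27	-0.19	-0.55	-0.48	-0.25
P	-0.3	-1.23	-3.53	-3.08	-0.82	-0.33	-1.29	-0.28	-3.44	-0.32	-0.56	-0.89	-0	-0.65	-4.46	-0.62	-0.7	-0.34	-0.41	-0.64
Q	-0.35	-0.58	-2.88	-2.43	-0.17	-0.32	-1.94	-0.37	-4.09	-0.33	-0.09	-0.24	-0.65	-0	-5.11	-0.03	-0.05	-0.31	-0.24	-0.01
R	-4.76	-5.69	-7.99	-7.54	-5.28	-4.79	-3.17	-4.74	-1.02	-4.78	-5.02	-5.35	-4.46	-5.11	-0	-5.08	-5.16	-4.8	-4.87	-5.1
S	-0.32	-0.61	-2.91	-2.46	-0.2	-0.29	-1.91	-0.34	-4.06	-0.3	-0.06	-0.27	-0.62	-0.03	-5.08	-0	-0.08	-0.28	-0.21	-0.02
T	-0.4	-0.53	-2.83	-2.38	-0.12	-0.37	-1.99	-0.42	-4.14	-0.38	-0.14	-0.19	-0.7	-0.05	-5.16	-0.08	-0	-0.36	-0.29	-0.06
V	-0.04	-0.89	-3.19	-2.74	-0.48	-0.01	-1.63	-0.06	-3.78	-0.02	-0.22	-0.55	-0.34	-0.31	-4.8	-0.28	-0.36	-0	-0.07	-0.3
W	-0.11	-0.82	-3.12	-2.67	-0.41	-0.08	-1.7	-0.13	-3.85	-0.09	-0.15	-0.48	-0.41	-0.24	-4.87	-0.21	-0.29	-0.07	-0	-0.23
Y	-0.34	-0.59	-2.89	-2.44	-0.18	-0.31	-1.93	-0.36	-4.08	-0.32	-0.08	-0.25	-0.64	-0.01	-5.1	-0.02	-0.06	-0.3	-0.23	-0
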