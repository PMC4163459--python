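wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.18	-0.2	0.03	0.03	-0.35	0.13	-0.14	-0.05	-0.12	-0.19	-0.11	0.02	0.11	-0.04	-0.15	0.11	0.12	0.02	-0.58	-0.35
C	-0.2	1.19	-0.51	-0.53	-0.43	-0.34	-0.34	-0.23	-0.54	-0.6	-0.52	-0.36	-0.28	-0.54	-0.36	0	-0.22	-0.19	-0.78	0.03
D	0.03	-0.51	0.39	0.34	-0.56	0.06	0.07	-0.24	0.01	-0.4	-0.26	0.21	-0.1	0.16	-0.13	0.03	-0.01	-0.21	-0.68	-0.43
E	0.03	-0.53	0.34	0.38	-0.54	0.02	0.07	-0.2	-0.01	-0.34	-0.21	0.14	-0.06	0.25	-0.11	0	-0.04	-0.18	-0.7	-0.43
F	-0.35	-0.43	-0.56	-0.54	0.91	-0.48	-0.18	0.1	-0.53	0.18	0.02	-0.35	-0.46	-0.47	-0.45	-0.32	-0.31	-0.12	0.04	0.7
G	0.13	-0.34	0.06	0.02	-0.48	0.48	-0.21	-0.26	-0.17	-0.41	-0.28	0.03	-0.05	-0.12	-0.26	0.11	0	-0.14	-0.7	-0.52
H	-0.14	-0.34	0.07	0.07	-0.18	-0.21	0.65	-0.24	0	-0.21	-0.21	0.16	-0.02	0.29	0.16	-0.08	-0.13	-0.22	-0.28	-0.01
I	-0.05	-0.23	-0.24	-0.2	0.1	-0.26	-0.24	0.45	-0.19	0.24	0.22	-0.18	-0.2	-0.2	-0.2	-0.14	0.01	0.37	-0.51	-0.09
K	-0.12	-0.54	0.01	-0.01	-0.53	-0.17	0	-0.19	0.47	-0.29	0.04	0.1	-0.11	0.07	0.34	-0.02	0	-0.24	-0.35	-0.44
L	-0.19	-0.6	-0.4	-0.34	0.18	-0.41	-0.21	0.24	-0.29	0.59	0.37	-0.29	-0.25	-0.18	-0.3	-0.28	-0.17	0.19	-0.18	-0.09
M	-0.11	-0.52	-0.26	-0.21	0.02	-0.28	-0.21	0.22	0.04	0.37	0.64	-0.17	-0.21	-0.1	-0.04	-0.16	-0.06	0.18	-0.42	-0.24
N	0.02	-0.36	0.21	0.14	-0.35	0.03	0.16	-0.18	0.1	-0.29	-0.17	0.2	-0.05	0.08	0	0.07	0.04	-0.17	-0.42	-0.21
P	0.11	-0.28	-0.1	-0.06	-0.46	-0.05	-0.02	-0.2	-0.11	-0.25	-0.21	-0.05	0.59	0.02	-0.02	0.09	0.03	-0.12	-0.56	-0.49
Q	-0.04	-0.54	0.16	0.25	-0.47	-0.12	0.29	-0.2	0.07	-0.18	-0.1	0.08	0.02	0.4	0.13	-0.05	-0.08	-0.19	-0.48	-0.4
R	-0.15	-0.36	-0.13	-0.11	-0.45	-0.26	0.16	-0.2	0.34	-0.3	-0.04	0	-0.02	0.13	0.61	-0.03	-0.09	-0.25	0.22	-0.42
S	0.11	0	0.03	0	-0.32	0.11	-0.08	-0.14	-0.02	-0.28	-0.16	0.07	0.09	-0.05	-0.03	0.16	0.13	-0.1	-0.25	-0.28
T	0.12	-0.22	-0.01	-0.04	-0.31	0	-0.13	0.01	0	-0.17	-0.06	0.04	0.03	-0.08	-0.09	0.13	0.26	0.03	-0.52	-0.27
V	0.02	-0.19	-0.21	-0.18	-0.12	-0.14	-0.22	0.37	-0.24	0.19	0.18	-0.17	-0.12	-0.19	-0.25	-0.1	0.03	0.43	-0.62	-0.25
W	-0.58	-0.78	-0.68	-0.7	0.04	-0.7	-0.28	-0.51	-0.35	-0.18	-0.42	-0.42	-0.56	-0.48	0.22	-0.25	-0.52	-0.62	1.73	-0.02
Y	-0.35	0.03	-0.43	-0.43	0.7	-0.52	-0.01	-0.09	-0.44	-0.09	-0.24	-0.21	-0.49	-0.4	-0.42	-0.28	-0.27	-0.25	-0.02	1.01
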