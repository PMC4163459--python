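wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.69	-0.8	-1.29	-0.18	-0.15	-0.59	-0.32	-1.9	-0.32	-0.15	-0.83	-0.7	-0.97	-1.42	-0.47	-0.6	-0.32	-0.01	-0.43
C	-0.69	-0	-1.49	-1.98	-0.51	-0.54	-1.28	-0.37	-2.59	-0.37	-0.54	-1.52	-1.39	-1.66	-2.11	-1.16	-1.29	-0.37	-0.68	-1.12
D	-0.8	-1.49	-0	-0.49	-0.98	-0.95	-0.21	-1.12	-1.1	-1.12	-0.95	-0.03	-0.1	-0.17	-0.62	-0.33	-0.2	-1.12	-0.81	-0.37
E	-1.29	-1.98	-0.49	-0	-1.47	-1.44	-0.7	-1.61	-0.61	-1.61	-1.44	-0.46	-0.59	-0.32	-0.13	-0.82	-0.69	-1.61	-1.3	-0.86
F	-0.18	-0.51	-0.98	-1.47	-0	-0.03	-0.77	-0.14	-2.08	-0.14	-0.03	-1.01	-0.88	-1.15	-1.6	-0.65	-0.78	-0.14	-0.17	-0.61
G	-0.15	-0.54	-0.95	-1.44	-0.03	-0	-0.74	-0.17	-2.05	-0.17	-0	-0.98	-0.85	-1.12	-1.57	-0.62	-0.75	-0.17	-0.14	-0.58
H	-0.59	-1.28	-0.21	-0.7	-0.77	-0.74	-0	-0.91	-1.31	-0.91	-0.74	-0.24	-0.11	-0.38	-0.83	-0.12	-0.01	-0.91	-0.6	-0.16
I	-0.32	-0.37	-1.12	-1.61	-0.14	-0.17	-0.91	-0	-2.22	-0	-0.17	-1.15	-1.02	-1.29	-1.74	-0.79	-0.92	-0	-0.31	-0.75
K	-1.9	-2.59	-1.1	-0.61	-2.08	-2.05	-1.31	-2.22	-0	-2.22	-2.05	-1.07	-1.2	-0.93	-0.48	-1.43	-1.3	-2.22	-1.91	-1.47
L	-0.32	-0.37	-1.12	-1.61	-0.14	-0.17	-0.91	-0	-2.22	-0	-0.17	-1.15	-1.02	-1.29	-1.74	-0.79	-0.92	-0	-0.31	-0.75
M	-0.15	-0.54	-0.95	-1.44	-0.03	-0	-0.74	-0.17	-2.05	-0.17	-0	-0.98	-0.85	-1.12	-1.57	-0.62	-0.75	-0.17	-0.14	-0.58
N	-0.83	-1.52	-0.03	-0.46	-1.01	-0.98	-0.24	-1.15	-1.07	-1.15	-0.98	-0	-0.13	-0.14	-0.59	-0.36	-0.23	-1.15	-0.84	-0.4
P	-0.7	-1.39	-0.1	-0.59	-0.88	-0.85	-0.11	-1.02	-1.2	-1.02	-0.85	-0.13	-0	-0.27	-0.72	-0.23	-0.1	-1.02	-0.71	-0.27
Q	-0.97	-1.66	-0.17	-0.32	-1.15	-1.12	-0.38	-1.29	-0.93	-1.29	-1.12	-0.14	-0.27	-0	-0.45	-0.5	-0.37	-1.29	-0.98	-0.54
R	-1.42	-2.11	-0.62	-0.13	-1.6	-1.57	-0.83	-1.74	-0.48	-1.74	-1.57	-0.59	-0.72	-0.45	-0	-0.95	-0.82	-1.74	-1.43	-0.99
S	-0.47	-1.16	-0.33	-0.82	-0.65	-0.62	-0.12	-0.79	-1.43	-0.79	-0.62	-0.36	-0.23	-0.5	-0.95	-0	-0.13	-0.79	-0.48	-0.04
T	-0.6	-1.29	-0.2	-0.69	-0.78	-0.75	-0.01	-0.92	-1.3	-0.92	-0.75	-0.23	-0.1	-0.37	-0.82	-0.13	-0	-0.92	-0.61	-0.17
V	-0.32	-0.37	-1.12	-1.61	-0.14	-0.17	-0.91	-0	-2.22	-0	-0.17	-1.15	-1.02	-1.29	-1.74	-0.79	-0.92	-0	-0.31	-0.75
W	-0.01	-0.68	-0.81	-1.3	-0.17	-0.14	-0.6	-0.31	-1.91	-0.31	-0.14	-0.84	-0.71	-0.98	-1.43	-0.48	-0.61	-0.31	-0	-0.44
Y	-0.43	-1.12	-0.37	-0.86	-0.61	-0.58	-0.16	-0.75	-1.47	-0.75	-0.58	-0.4	-0.27	-0.54	-0.99	-0.04	-0.17	-0.75	-0.44	-0
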