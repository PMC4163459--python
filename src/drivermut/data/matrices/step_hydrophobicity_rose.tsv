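wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.17	-0.12	-0.12	-0.14	-0.02	-0.04	-0.14	-0.22	-0.11	-0.11	-0.11	-0.1	-0.12	-0.1	-0.08	-0.04	-0.12	-0.11	-0.02
C	-0.17	-0	-0.29	-0.29	-0.03	-0.19	-0.13	-0.03	-0.39	-0.06	-0.06	-0.28	-0.27	-0.29	-0.27	-0.25	-0.21	-0.05	-0.06	-0.15
D	-0.12	-0.29	-0	-0	-0.26	-0.1	-0.16	-0.26	-0.1	-0.23	-0.23	-0.01	-0.02	-0	-0.02	-0.04	-0.08	-0.24	-0.23	-0.14
E	-0.12	-0.29	-0	-0	-0.26	-0.1	-0.16	-0.26	-0.1	-0.23	-0.23	-0.01	-0.02	-0	-0.02	-0.04	-0.08	-0.24	-0.23	-0.14
F	-0.14	-0.03	-0.26	-0.26	-0	-0.16	-0.1	-0	-0.36	-0.03	-0.03	-0.25	-0.24	-0.26	-0.24	-0.22	-0.18	-0.02	-0.03	-0.12
G	-0.02	-0.19	-0.1	-0.1	-0.16	-0	-0.06	-0.16	-0.2	-0.13	-0.13	-0.09	-0.08	-0.1	-0.08	-0.06	-0.02	-0.14	-0.13	-0.04
H	-0.04	-0.13	-0.16	-0.16	-0.1	-0.06	-0	-0.1	-0.26	-0.07	-0.07	-0.15	-0.14	-0.16	-0.14	-0.12	-0.08	-0.08	-0.07	-0.02
I	-0.14	-0.03	-0.26	-0.26	-0	-0.16	-0.1	-0	-0.36	-0.03	-0.03	-0.25	-0.24	-0.26	-0.24	-0.22	-0.18	-0.02	-0.03	-0.12
K	-0.22	-0.39	-0.1	-0.1	-0.36	-0.2	-0.26	-0.36	-0	-0.33	-0.33	-0.11	-0.12	-0.1	-0.12	-0.14	-0.18	-0.34	-0.33	-0.24
L	-0.11	-0.06	-0.23	-0.23	-0.03	-0.13	-0.07	-0.03	-0.33	-0	-0	-0.22	-0.21	-0.23	-0.21	-0.19	-0.15	-0.01	-0	-0.09
M	-0.11	-0.06	-0.23	-0.23	-0.03	-0.13	-0.07	-0.03	-0.33	-0	-0	-0.22	-0.21	-0.23	-0.21	-0.19	-0.15	-0.01	-0	-0.09
N	-0.11	-0.28	-0.01	-0.01	-0.25	-0.09	-0.15	-0.25	-0.11	-0.22	-0.22	-0	-0.01	-0.01	-0.01	-0.03	-0.07	-0.23	-0.22	-0.13
P	-0.1	-0.27	-0.02	-0.02	-0.24	-0.08	-0.14	-0.24	-0.12	-0.21	-0.21	-0.01	-0	-0.02	-0	-0.02	-0.06	-0.22	-0.21	-0.12
Q	-0.12	-0.29	-0	-0	-0.26	-0.1	-0.16	-0.26	-0.1	-0.23	-0.23	-0.01	-0.02	-0	-0.02	-0.04	-0.08	-0.24	-0.23	-0.14
R	-0.1	-0.27	-0.02	-0.02	-0.24	-0.08	-0.14	-0.24	-0.12	-0.21	-0.21	-0.01	-0	-0.02	-0	-0.02	-0.06	-0.22	-0.21	-0.12
S	-0.08	-0.25	-0.04	-0.04	-0.22	-0.06	-0.12	-0.22	-0.14	-0.19	-0.19	-0.03	-0.02	-0.04	-0.02	-0	-0.04	-0.2	-0.19	-0.1
T	-0.04	-0.21	-0.08	-0.08	-0.18	-0.02	-0.08	-0.18	-0.18	-0.15	-0.15	-0.07	-0.06	-0.08	-0.06	-0.04	-0	-0.16	-0.15	-0.06
V	-0.12	-0.05	-0.24	-0.24	-0.02	-0.14	-0.08	-0.02	-0.34	-0.01	-0.01	-0.23	-0.22	-0.24	-0.22	-0.2	-0.16	-0	-0.01	-0.1
W	-0.11	-0.06	-0.23	-0.23	-0.03	-0.13	-0.07	-0.03	-0.33	-0	-0	-0.22	-0.21	-0.23	-0.21	-0.19	-0.15	-0.01	-0	-0.09
Y	-0.02	-0.15	-0.14	-0.14	-0.12	-0.04	-0.02	-0.12	-0.24	-0.09	-0.09	-0.13	-0.12	-0.14	-0.12	-0.1	-0.06	-0.1	-0.09	-0
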