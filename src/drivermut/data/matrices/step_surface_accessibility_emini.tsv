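wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.421	-0.468	-0.63	-0.12	-0.101	-0.365	-0.212	-0.73	-0.212	-0.101	-0.481	-0.421	-0.533	-0.66	-0.3	-0.369	-0.209	-0.007	-0.274
C	-0.421	-0	-0.889	-1.051	-0.301	-0.32	-0.786	-0.209	-1.151	-0.209	-0.32	-0.902	-0.842	-0.954	-1.081	-0.721	-0.79	-0.212	-0.414	-0.695
D	-0.468	-0.889	-0	-0.162	-0.588	-0.569	-0.103	-0.68	-0.262	-0.68	-0.569	-0.013	-0.047	-0.065	-0.192	-0.168	-0.099	-0.677	-0.475	-0.194
E	-0.63	-1.051	-0.162	-0	-0.75	-0.731	-0.265	-0.842	-0.1	-0.842	-0.731	-0.149	-0.209	-0.097	-0.03	-0.33	-0.261	-0.839	-0.637	-0.356
F	-0.12	-0.301	-0.588	-0.75	-0	-0.019	-0.485	-0.092	-0.85	-0.092	-0.019	-0.601	-0.541	-0.653	-0.78	-0.42	-0.489	-0.089	-0.113	-0.394
G	-0.101	-0.32	-0.569	-0.731	-0.019	-0	-0.466	-0.111	-0.831	-0.111	-0	-0.582	-0.522	-0.634	-0.761	-0.401	-0.47	-0.108	-0.094	-0.375
H	-0.365	-0.786	-0.103	-0.265	-0.485	-0.466	-0	-0.577	-0.365	-0.577	-0.466	-0.116	-0.056	-0.168	-0.295	-0.065	-0.004	-0.574	-0.372	-0.091
I	-0.212	-0.209	-0.68	-0.842	-0.092	-0.111	-0.577	-0	-0.942	-0	-0.111	-0.693	-0.633	-0.745	-0.872	-0.512	-0.581	-0.003	-0.205	-0.486
K	-0.73	-1.151	-0.262	-0.1	-0.85	-0.831	-0.365	-0.942	-0	-0.942	-0.831	-0.249	-0.309	-0.197	-0.07	-0.43	-0.361	-0.939	-0.737	-0.456
L	-0.212	-0.209	-0.68	-0.842	-0.092	-0.111	-0.577	-0	-0.942	-0	-0.111	-0.693	-0.633	-0.745	-0.872	-0.512	-0.581	-0.003	-0.205	-0.486
M	-0.101	-0.32	-0.569	-0.731	-0.019	-0	-0.466	-0.111	-0.831	-0.111	-0	-0.582	-0.522	-0.634	-0.761	-0.401	-0.47	-0.108	-0.094	-0.375
N	-0.481	-0.902	-0.013	-0.149	-0.601	-0.582	-0.116	-0.693	-0.249	-0.693	-0.582	-0	-0.06	-0.052	-0.179	-0.181	-0.112	-0.69	-0.488	-0.207
P	-0.421	-0.842	-0.047	-0.209	-0.541	-0.522	-0.056	-0.633	-0.309	-0.633	-0.522	-0.06	-0	-0.112	-0.239	-0.121	-0.052	-0.63	-0.428	-0.147
Q	-0.533	-0.954	-0.065	-0.097	-0.653	-0.634	-0.168	-0.745	-0.197	-0.745	-0.634	-0.052	-0.112	-0	-0.127	-0.233	-0.164	-0.742	-0.54	-0.259
R	-0.66	-1.081	-0.192	-0.03	-0.78	-0.761	-0.295	-0.872	-0.07	-0.872	-0.761	-0.179	-0.239	-0.127	-0	-0.36	-0.291	-0.869	-0.667	-0.386
S	-0.3	-0.721	-0.168	-0.33	-0.42	-0.401	-0.065	-0.512	-0.43	-0.512	-0.401	-0.181	-0.121	-0.233	-0.36	-0	-0.069	-0.509	-0.307	-0.026
T	-0.369	-0.79	-0.099	-0.261	-0.489	-0.47	-0.004	-0.581	-0.361	-0.581	-0.47	-0.112	-0.052	-0.164	-0.291	-0.069	-0	-0.578	-0.376	-0.095
V	-0.209	-0.212	-0.677	-0.839	-0.089	-0.108	-0.574	-0.003	-0.939	-0.003	-0.108	-0.69	-0.63	-0.742	-0.869	-0.509	-0.578	-0	-0.202	-0.483
W	-0.007	-0.414	-0.475	-0.637	-0.113	-0.094	-0.372	-0.205	-0.737	-0.205	-0.094	-0.488	-0.428	-0.54	-0.667	-0.307	-0.376	-0.202	-0	-0.281
Y	-0.274	-0.695	-0.194	-0.356	-0.394	-0.375	-0.091	-0.486	-0.456	-0.486	-0.375	-0.207	-0.147	-0.259	-0.386	-0.026	-0.095	-0.483	-0.281	-0
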