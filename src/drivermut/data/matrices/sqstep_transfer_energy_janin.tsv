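wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.4761	-0.64	-1.6641	-0.0324	-0.0225	-0.3481	-0.1024	-3.61	-0.1024	-0.0225	-0.6889	-0.49	-0.9409	-2.0164	-0.2209	-0.36	-0.1024	-0.0001	-0.1849
C	-0.4761	-0	-2.2201	-3.9204	-0.2601	-0.2916	-1.6384	-0.1369	-6.7081	-0.1369	-0.2916	-2.3104	-1.9321	-2.7556	-4.4521	-1.3456	-1.6641	-0.1369	-0.4624	-1.2544
D	-0.64	-2.2201	-0	-0.2401	-0.9604	-0.9025	-0.0441	-1.2544	-1.21	-1.2544	-0.9025	-0.0009	-0.01	-0.0289	-0.3844	-0.1089	-0.04	-1.2544	-0.6561	-0.1369
E	-1.6641	-3.9204	-0.2401	-0	-2.1609	-2.0736	-0.49	-2.5921	-0.3721	-2.5921	-2.0736	-0.2116	-0.3481	-0.1024	-0.0169	-0.6724	-0.4761	-2.5921	-1.69	-0.7396
F	-0.0324	-0.2601	-0.9604	-2.1609	-0	-0.0009	-0.5929	-0.0196	-4.3264	-0.0196	-0.0009	-1.0201	-0.7744	-1.3225	-2.56	-0.4225	-0.6084	-0.0196	-0.0289	-0.3721
G	-0.0225	-0.2916	-0.9025	-2.0736	-0.0009	-0	-0.5476	-0.0289	-4.2025	-0.0289	-0	-0.9604	-0.7225	-1.2544	-2.4649	-0.3844	-0.5625	-0.0289	-0.0196	-0.3364
H	-0.3481	-1.6384	-0.0441	-0.49	-0.5929	-0.5476	-0	-0.8281	-1.7161	-0.8281	-0.5476	-0.0576	-0.0121	-0.1444	-0.6889	-0.0144	-0.0001	-0.8281	-0.36	-0.0256
I	-0.1024	-0.1369	-1.2544	-2.5921	-0.0196	-0.0289	-0.8281	-0	-4.9284	-0	-0.0289	-1.3225	-1.0404	-1.6641	-3.0276	-0.6241	-0.8464	-0	-0.0961	-0.5625
K	-3.61	-6.7081	-1.21	-0.3721	-4.3264	-4.2025	-1.7161	-4.9284	-0	-4.9284	-4.2025	-1.1449	-1.44	-0.8649	-0.2304	-2.0449	-1.69	-4.9284	-3.6481	-2.1609
L	-0.1024	-0.1369	-1.2544	-2.5921	-0.0196	-0.0289	-0.8281	-0	-4.9284	-0	-0.0289	-1.3225	-1.0404	-1.6641	-3.0276	-0.6241	-0.8464	-0	-0.0961	-0.5625
M	-0.0225	-0.2916	-0.9025	-2.0736	-0.0009	-0	-0.5476	-0.0289	-4.2025	-0.0289	-0	-0.9604	-0.7225	-1.2544	-2.4649	-0.3844	-0.5625	-0.0289	-0.0196	-0.3364
N	-0.6889	-2.3104	-0.0009	-0.2116	-1.0201	-0.9604	-0.0576	-1.3225	-1.1449	-1.3225	-0.9604	-0	-0.0169	-0.0196	-0.3481	-0.1296	-0.0529	-1.3225	-0.7056	-0.16
P	-0.49	-1.9321	-0.01	-0.3481	-0.7744	-0.7225	-0.0121	-1.0404	-1.44	-1.0404	-0.7225	-0.0169	-0	-0.0729	-0.5184	-0.0529	-0.01	-1.0404	-0.5041	-0.0729
Q	-0.9409	-2.7556	-0.0289	-0.1024	-1.3225	-1.2544	-0.1444	-1.6641	-0.8649	-1.6641	-1.2544	-0.0196	-0.0729	-0	-0.2025	-0.25	-0.1369	-1.6641	-0.9604	-0.2916
R	-2.0164	-4.4521	-0.3844	-0.0169	-2.56	-2.4649	-0.6889	-3.0276	-0.2304	-3.0276	-2.4649	-0.3481	-0.5184	-0.2025	-0	-0.9025	-0.6724	-3.0276	-2.0449	-0.9801
S	-0.2209	-1.3456	-0.1089	-0.6724	-0.4225	-0.3844	-0.0144	-0.6241	-2.0449	-0.6241	-0.3844	-0.1296	-0.0529	-0.25	-0.9025	-0	-0.0169	-0.6241	-0.2304	-0.0016
T	-0.36	-1.6641	-0.04	-0.4761	-0.6084	-0.5625	-0.0001	-0.8464	-1.69	-0.8464	-0.5625	-0.0529	-0.01	-0.1369	-0.6724	-0.0169	-0	-0.8464	-0.3721	-0.0289
V	-0.1024	-0.1369	-1.2544	-2.5921	-0.0196	-0.0289	-0.8281	-0	-4.9284	-0	-0.0289	-1.3225	-1.0404	-1.6641	-3.0276	-0.6241	-0.8464	-0	-0.0961	-0.5625
W	-0.0001	-0.4624	-0.6561	-1.69	-0.0289	-0.0196	-0.36	-0.0961	-3.6481	-0.0961	-0.0196	-0.7056	-0.5041	-0.9604	-2.0449	-0.2304	-0.3721	-0.0961	-0	-0.1936
Y	-0.1849	-1.2544	-0.1369	-0.7396	-0.3721	-0.3364	-0.0256	-0.5625	-2.1609	-0.5625	-0.3364	-0.16	-0.0729	-0.2916	-0.9801	-0.0016	-0.0289	-0.5625	-0.1936	-0
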