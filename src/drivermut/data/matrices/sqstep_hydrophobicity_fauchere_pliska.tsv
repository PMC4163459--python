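wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-1.5129	-1.1664	-0.9025	-2.1904	-0.0961	-0.0324	-2.2201	-1.69	-1.9321	-0.8464	-0.8281	-0.1681	-0.2809	-1.7424	-0.1225	-0.0025	-0.8281	-3.7636	-0.4225
C	-1.5129	-0	-5.3361	-4.7524	-0.0625	-2.3716	-1.9881	-0.0676	-6.4009	-0.0256	-0.0961	-4.5796	-0.6724	-3.0976	-6.5025	-2.4964	-1.6384	-0.1024	-0.5041	-0.3364
D	-1.1664	-5.3361	-0	-0.0169	-6.5536	-0.5929	-0.81	-6.6049	-0.0484	-6.1009	-4	-0.0289	-2.2201	-0.3025	-0.0576	-0.5329	-1.0609	-3.9601	-9.1204	-2.9929
E	-0.9025	-4.7524	-0.0169	-0	-5.9049	-0.4096	-0.5929	-5.9536	-0.1225	-5.4756	-3.4969	-0.0016	-1.8496	-0.1764	-0.1369	-0.36	-0.81	-3.4596	-8.3521	-2.56
F	-2.1904	-0.0625	-6.5536	-5.9049	-0	-3.2041	-2.7556	-0.0001	-7.7284	-0.0081	-0.3136	-5.7121	-1.1449	-4.0401	-7.84	-3.3489	-2.3409	-0.3249	-0.2116	-0.6889
G	-0.0961	-2.3716	-0.5929	-0.4096	-3.2041	-0	-0.0169	-3.24	-0.9801	-2.89	-1.5129	-0.36	-0.5184	-0.0484	-1.0201	-0.0016	-0.0676	-1.4884	-5.0625	-0.9216
H	-0.0324	-1.9881	-0.81	-0.5929	-2.7556	-0.0169	-0	-2.7889	-1.2544	-2.4649	-1.21	-0.5329	-0.3481	-0.1225	-1.2996	-0.0289	-0.0169	-1.1881	-4.4944	-0.6889
I	-2.2201	-0.0676	-6.6049	-5.9536	-0.0001	-3.24	-2.7889	-0	-7.7841	-0.01	-0.3249	-5.76	-1.1664	-4.0804	-7.8961	-3.3856	-2.3716	-0.3364	-0.2025	-0.7056
K	-1.69	-6.4009	-0.0484	-0.1225	-7.7284	-0.9801	-1.2544	-7.7841	-0	-7.2361	-4.9284	-0.1521	-2.9241	-0.5929	-0.0004	-0.9025	-1.5625	-4.8841	-10.4976	-3.8025
L	-1.9321	-0.0256	-6.1009	-5.4756	-0.0081	-2.89	-2.4649	-0.01	-7.2361	-0	-0.2209	-5.29	-0.9604	-3.6864	-7.3441	-3.0276	-2.0736	-0.2304	-0.3025	-0.5476
M	-0.8464	-0.0961	-4	-3.4969	-0.3136	-1.5129	-1.21	-0.3249	-4.9284	-0.2209	-0	-3.3489	-0.2601	-2.1025	-5.0176	-1.6129	-0.9409	-0.0001	-1.0404	-0.0729
N	-0.8281	-4.5796	-0.0289	-0.0016	-5.7121	-0.36	-0.5329	-5.76	-0.1521	-5.29	-3.3489	-0	-1.7424	-0.1444	-0.1681	-0.3136	-0.7396	-3.3124	-8.1225	-2.4336
P	-0.1681	-0.6724	-2.2201	-1.8496	-1.1449	-0.5184	-0.3481	-1.1664	-2.9241	-0.9604	-0.2601	-1.7424	-0	-0.8836	-2.9929	-0.5776	-0.2116	-0.25	-2.3409	-0.0576
Q	-0.2809	-3.0976	-0.3025	-0.1764	-4.0401	-0.0484	-0.1225	-4.0804	-0.5929	-3.6864	-2.1025	-0.1444	-0.8836	-0	-0.6241	-0.0324	-0.2304	-2.0736	-6.1009	-1.3924
R	-1.7424	-6.5025	-0.0576	-0.1369	-7.84	-1.0201	-1.2996	-7.8961	-0.0004	-7.3441	-5.0176	-0.1681	-2.9929	-0.6241	-0	-0.9409	-1.6129	-4.9729	-10.6276	-3.8809
S	-0.1225	-2.4964	-0.5329	-0.36	-3.3489	-0.0016	-0.0289	-3.3856	-0.9025	-3.0276	-1.6129	-0.3136	-0.5776	-0.0324	-0.9409	-0	-0.09	-1.5876	-5.2441	-1
T	-0.0025	-1.6384	-1.0609	-0.81	-2.3409	-0.0676	-0.0169	-2.3716	-1.5625	-2.0736	-0.9409	-0.7396	-0.2116	-0.2304	-1.6129	-0.09	-0	-0.9216	-3.9601	-0.49
V	-0.8281	-0.1024	-3.9601	-3.4596	-0.3249	-1.4884	-1.1881	-0.3364	-4.8841	-0.2304	-0.0001	-3.3124	-0.25	-2.0736	-4.9729	-1.5876	-0.9216	-0	-1.0609	-0.0676
W	-3.7636	-0.5041	-9.1204	-8.3521	-0.2116	-5.0625	-4.4944	-0.2025	-10.4976	-0.3025	-1.0404	-8.1225	-2.3409	-6.1009	-10.6276	-5.2441	-3.9601	-1.0609	-0	-1.6641
Y	-0.4225	-0.3364	-2.9929	-2.56	-0.6889	-0.9216	-0.6889	-0.7056	-3.8025	-0.5476	-0.0729	-2.4336	-0.0576	-1.3924	-3.8809	-1	-0.49	-0.0676	-1.6641	-0
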