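wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.1089	-2.3104	-1.8496	-0.3249	-0.0196	-1.0404	-0.5776	-4.4944	-0.1936	-0.0004	-1.96	-0.25	-2.1609	-9.9225	-0.64	-0.4489	-0.2116	-0.0361	-0.1296
C	-0.1089	-0	-1.4161	-1.0609	-0.81	-0.0361	-0.4761	-1.1881	-3.2041	-0.5929	-0.1225	-1.1449	-0.0289	-1.2996	-7.9524	-0.2209	-0.1156	-0.6241	-0.2704	-0.0009
D	-2.3104	-1.4161	-0	-0.0256	-4.3681	-1.9044	-0.25	-5.1984	-0.36	-3.8416	-2.3716	-0.0144	-1.0404	-0.0025	-2.6569	-0.5184	-0.7225	-3.9204	-2.9241	-1.3456
E	-1.8496	-1.0609	-0.0256	-0	-3.7249	-1.4884	-0.1156	-4.4944	-0.5776	-3.24	-1.9044	-0.0016	-0.7396	-0.0121	-3.2041	-0.3136	-0.4761	-3.3124	-2.4025	-1
F	-0.3249	-0.81	-4.3681	-3.7249	-0	-0.5041	-2.5281	-0.0361	-7.2361	-0.0169	-0.3025	-3.8809	-1.1449	-4.1616	-13.8384	-1.8769	-1.5376	-0.0121	-0.1444	-0.8649
G	-0.0196	-0.0361	-1.9044	-1.4884	-0.5041	-0	-0.7744	-0.81	-3.9204	-0.3364	-0.0256	-1.5876	-0.1296	-1.7689	-9.0601	-0.4356	-0.2809	-0.36	-0.1089	-0.0484
H	-1.0404	-0.4761	-0.25	-0.1156	-2.5281	-0.7744	-0	-3.1684	-1.21	-2.1316	-1.0816	-0.1444	-0.2704	-0.2025	-4.5369	-0.0484	-0.1225	-2.1904	-1.4641	-0.4356
I	-0.5776	-1.1881	-5.1984	-4.4944	-0.0361	-0.81	-3.1684	-0	-8.2944	-0.1024	-0.5476	-4.6656	-1.5876	-4.9729	-15.2881	-2.4336	-2.0449	-0.09	-0.3249	-1.2544
K	-4.4944	-3.2041	-0.36	-0.5776	-7.2361	-3.9204	-1.21	-8.2944	-0	-6.5536	-4.5796	-0.5184	-2.6244	-0.4225	-1.0609	-1.7424	-2.1025	-6.6564	-5.3361	-3.0976
L	-0.1936	-0.5929	-3.8416	-3.24	-0.0169	-0.3364	-2.1316	-0.1024	-6.5536	-0	-0.1764	-3.3856	-0.8836	-3.6481	-12.8881	-1.5376	-1.2321	-0.0004	-0.0625	-0.64
M	-0.0004	-0.1225	-2.3716	-1.9044	-0.3025	-0.0256	-1.0816	-0.5476	-4.5796	-0.1764	-0	-2.0164	-0.2704	-2.2201	-10.0489	-0.6724	-0.4761	-0.1936	-0.0289	-0.1444
N	-1.96	-1.1449	-0.0144	-0.0016	-3.8809	-1.5876	-0.1444	-4.6656	-0.5184	-3.3856	-2.0164	-0	-0.81	-0.0049	-3.0625	-0.36	-0.5329	-3.4596	-2.5281	-1.0816
P	-0.25	-0.0289	-1.0404	-0.7396	-1.1449	-0.1296	-0.2704	-1.5876	-2.6244	-0.8836	-0.2704	-0.81	-0	-0.9409	-7.0225	-0.09	-0.0289	-0.9216	-0.4761	-0.0196
Q	-2.1609	-1.2996	-0.0025	-0.0121	-4.1616	-1.7689	-0.2025	-4.9729	-0.4225	-3.6481	-2.2201	-0.0049	-0.9409	-0	-2.8224	-0.4489	-0.64	-3.7249	-2.7556	-1.2321
R	-9.9225	-7.9524	-2.6569	-3.2041	-13.8384	-9.0601	-4.5369	-15.2881	-1.0609	-12.8881	-10.0489	-3.0625	-7.0225	-2.8224	-0	-5.5225	-6.1504	-13.0321	-11.1556	-7.7841
S	-0.64	-0.2209	-0.5184	-0.3136	-1.8769	-0.4356	-0.0484	-2.4336	-1.7424	-1.5376	-0.6724	-0.36	-0.09	-0.4489	-5.5225	-0	-0.0169	-1.5876	-0.9801	-0.1936
T	-0.4489	-0.1156	-0.7225	-0.4761	-1.5376	-0.2809	-0.1225	-2.0449	-2.1025	-1.2321	-0.4761	-0.5329	-0.0289	-0.64	-6.1504	-0.0169	-0	-1.2769	-0.7396	-0.0961
V	-0.2116	-0.6241	-3.9204	-3.3124	-0.0121	-0.36	-2.1904	-0.09	-6.6564	-0.0004	-0.1936	-3.4596	-0.9216	-3.7249	-13.0321	-1.5876	-1.2769	-0	-0.0729	-0.6724
W	-0.0361	-0.2704	-2.9241	-2.4025	-0.1444	-0.1089	-1.4641	-0.3249	-5.3361	-0.0625	-0.0289	-2.5281	-0.4761	-2.7556	-11.1556	-0.9801	-0.7396	-0.0729	-0	-0.3025
Y	-0.1296	-0.0009	-1.3456	-1	-0.8649	-0.0484	-0.4356	-1.2544	-3.0976	-0.64	-0.1444	-1.0816	-0.0196	-1.2321	-7.7841	-0.1936	-0.0961	-0.6724	-0.3025	-0
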