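wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.0289	-0.0144	-0.0144	-0.0196	-0.0004	-0.0016	-0.0196	-0.0484	-0.0121	-0.0121	-0.0121	-0.01	-0.0144	-0.01	-0.0064	-0.0016	-0.0144	-0.0121	-0.0004
C	-0.0289	-0	-0.0841	-0.0841	-0.0009	-0.0361	-0.0169	-0.0009	-0.1521	-0.0036	-0.0036	-0.0784	-0.0729	-0.0841	-0.0729	-0.0625	-0.0441	-0.0025	-0.0036	-0.0225
D	-0.0144	-0.0841	-0	-0	-0.0676	-0.01	-0.0256	-0.0676	-0.01	-0.0529	-0.0529	-0.0001	-0.0004	-0	-0.0004	-0.0016	-0.0064	-0.0576	-0.0529	-0.0196
E	-0.0144	-0.0841	-0	-0	-0.0676	-0.01	-0.0256	-0.0676	-0.01	-0.0529	-0.0529	-0.0001	-0.0004	-0	-0.0004	-0.0016	-0.0064	-0.0576	-0.0529	-0.0196
F	-0.0196	-0.0009	-0.0676	-0.0676	-0	-0.0256	-0.01	-0	-0.1296	-0.0009	-0.0009	-0.0625	-0.0576	-0.0676	-0.0576	-0.0484	-0.0324	-0.0004	-0.0009	-0.0144
G	-0.0004	-0.0361	-0.01	-0.01	-0.0256	-0	-0.0036	-0.0256	-0.04	-0.0169	-0.0169	-0.0081	-0.0064	-0.01	-0.0064	-0.0036	-0.0004	-0.0196	-0.0169	-0.0016
H	-0.0016	-0.0169	-0.0256	-0.0256	-0.01	-0.0036	-0	-0.01	-0.0676	-0.0049	-0.0049	-0.0225	-0.0196	-0.0256	-0.0196	-0.0144	-0.0064	-0.0064	-0.0049	-0.0004
I	-0.0196	-0.0009	-0.0676	-0.0676	-0	-0.0256	-0.01	-0	-0.1296	-0.0009	-0.0009	-0.0625	-0.0576	-0.0676	-0.0576	-0.0484	-0.0324	-0.0004	-0.0009	-0.0144
K	-0.0484	-0.1521	-0.01	-0.01	-0.1296	-0.04	-0.0676	-0.1296	-0	-0.1089	-0.1089	-0.0121	-0.0144	-0.01	-0.0144	-0.0196	-0.0324	-0.1156	-0.1089	-0.0576
L	-0.0121	-0.0036	-0.0529	-0.0529	-0.0009	-0.0169	-0.0049	-0.0009	-0.1089	-0	-0	-0.0484	-0.0441	-0.0529	-0.0441	-0.0361	-0.0225	-0.0001	-0	-0.0081
M	-0.0121	-0.0036	-0.0529	-0.0529	-0.0009	-0.0169	-0.0049	-0.0009	-0.1089	-0	-0	-0.0484	-0.0441	-0.0529	-0.0441	-0.0361	-0.0225	-0.0001	-0	-0.0081
N	-0.0121	-0.0784	-0.0001	-0.0001	-0.0625	-0.0081	-0.0225	-0.0625	-0.0121	-0.0484	-0.0484	-0	-0.0001	-0.0001	-0.0001	-0.0009	-0.0049	-0.0529	-0.0484	-0.0169
P	-0.01	-0.0729	-0.0004	-0.0004	-0.0576	-0.0064	-0.0196	-0.0576	-0.0144	-0.0441	-0.0441	-0.0001	-0	-0.0004	-0	-0.0004	-0.0036	-0.0484	-0.0441	-0.0144
Q	-0.0144	-0.0841	-0	-0	-0.0676	-0.01	-0.0256	-0.0676	-0.01	-0.0529	-0.0529	-0.0001	-0.0004	-0	-0.0004	-0.0016	-0.0064	-0.0576	-0.0529	-0.0196
R	-0.01	-0.0729	-0.0004	-0.0004	-0.0576	-0.0064	-0.0196	-0.0576	-0.0144	-0.0441	-0.0441	-0.0001	-0	-0.0004	-0	-0.0004	-0.0036	-0.0484	-0.0441	-0.0144
S	-0.0064	-0.0625	-0.0016	-0.0016	-0.0484	-0.0036	-0.0144	-0.0484	-0.0196	-0.0361	-0.0361	-0.0009	-0.0004	-0.0016	-0.0004	-0	-0.0016	-0.04	-0.0361	-0.01
T	-0.0016	-0.0441	-0.0064	-0.0064	-0.0324	-0.0004	-0.0064	-0.0324	-0.0324	-0.0225	-0.0225	-0.0049	-0.0036	-0.0064	-0.0036	-0.0016	-0	-0.0256	-0.0225	-0.0036
V	-0.0144	-0.0025	-0.0576	-0.0576	-0.0004	-0.0196	-0.0064	-0.0004	-0.1156	-0.0001	-0.0001	-0.0529	-0.0484	-0.0576	-0.0484	-0.04	-0.0256	-0	-0.0001	-0.01
W	-0.0121	-0.0036	-0.0529	-0.0529	-0.0009	-0.0169	-0.0049	-0.0009	-0.1089	-0	-0	-0.0484	-0.0441	-0.0529	-0.0441	-0.0361	-0.0225	-0.0001	-0	-0.0081
Y	-0.0004	-0.0225	-0.0196	-0.0196	-0.0144	-0.0016	-0.0004	-0.0144	-0.0576	-0.0081	-0.0081	-0.0169	-0.0144	-0.0196	-0.0144	-0.01	-0.0036	-0.01	-0.0081	-0
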