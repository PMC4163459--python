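wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.177241	-0.219024	-0.3969	-0.0144	-0.010201	-0.133225	-0.044944	-0.5329	-0.044944	-0.010201	-0.231361	-0.177241	-0.284089	-0.4356	-0.09	-0.136161	-0.043681	-4.9e-05	-0.075076
C	-0.177241	-0	-0.790321	-1.1046	-0.090601	-0.1024	-0.617796	-0.043681	-1.3248	-0.043681	-0.1024	-0.813604	-0.708964	-0.910116	-1.16856	-0.519841	-0.6241	-0.044944	-0.171396	-0.483025
D	-0.219024	-0.790321	-0	-0.026244	-0.345744	-0.323761	-0.010609	-0.4624	-0.068644	-0.4624	-0.323761	-0.000169	-0.002209	-0.004225	-0.036864	-0.028224	-0.009801	-0.458329	-0.225625	-0.037636
E	-0.3969	-1.1046	-0.026244	-0	-0.5625	-0.534361	-0.070225	-0.708964	-0.01	-0.708964	-0.534361	-0.022201	-0.043681	-0.009409	-0.0009	-0.1089	-0.068121	-0.703921	-0.405769	-0.126736
F	-0.0144	-0.090601	-0.345744	-0.5625	-0	-0.000361	-0.235225	-0.008464	-0.7225	-0.008464	-0.000361	-0.361201	-0.292681	-0.426409	-0.6084	-0.1764	-0.239121	-0.007921	-0.012769	-0.155236
G	-0.010201	-0.1024	-0.323761	-0.534361	-0.000361	-0	-0.217156	-0.012321	-0.690561	-0.012321	-0	-0.338724	-0.272484	-0.401956	-0.579121	-0.160801	-0.2209	-0.011664	-0.008836	-0.140625
H	-0.133225	-0.617796	-0.010609	-0.070225	-0.235225	-0.217156	-0	-0.332929	-0.133225	-0.332929	-0.217156	-0.013456	-0.003136	-0.028224	-0.087025	-0.004225	-1.6e-05	-0.329476	-0.138384	-0.008281
I	-0.044944	-0.043681	-0.4624	-0.708964	-0.008464	-0.012321	-0.332929	-0	-0.887364	-0	-0.012321	-0.480249	-0.400689	-0.555025	-0.760384	-0.262144	-0.337561	-9e-06	-0.042025	-0.236196
K	-0.5329	-1.3248	-0.068644	-0.01	-0.7225	-0.690561	-0.133225	-0.887364	-0	-0.887364	-0.690561	-0.062001	-0.095481	-0.038809	-0.0049	-0.1849	-0.130321	-0.881721	-0.543169	-0.207936
L	-0.044944	-0.043681	-0.4624	-0.708964	-0.008464	-0.012321	-0.332929	-0	-0.887364	-0	-0.012321	-0.480249	-0.400689	-0.555025	-0.760384	-0.262144	-0.337561	-9e-06	-0.042025	-0.236196
M	-0.010201	-0.1024	-0.323761	-0.534361	-0.000361	-0	-0.217156	-0.012321	-0.690561	-0.012321	-0	-0.338724	-0.272484	-0.401956	-0.579121	-0.160801	-0.2209	-0.011664	-0.008836	-0.140625
N	-0.231361	-0.813604	-0.000169	-0.022201	-0.361201	-0.338724	-0.013456	-0.480249	-0.062001	-0.480249	-0.338724	-0	-0.0036	-0.002704	-0.032041	-0.032761	-0.012544	-0.4761	-0.238144	-0.042849
P	-0.177241	-0.708964	-0.002209	-0.043681	-0.292681	-0.272484	-0.003136	-0.400689	-0.095481	-0.400689	-0.272484	-0.0036	-0	-0.012544	-0.057121	-0.014641	-0.002704	-0.3969	-0.183184	-0.021609
Q	-0.284089	-0.910116	-0.004225	-0.009409	-0.426409	-0.401956	-0.028224	-0.555025	-0.038809	-0.555025	-0.401956	-0.002704	-0.012544	-0	-0.016129	-0.054289	-0.026896	-0.550564	-0.2916	-0.067081
R	-0.4356	-1.16856	-0.036864	-0.0009	-0.6084	-0.579121	-0.087025	-0.760384	-0.0049	-0.760384	-0.579121	-0.032041	-0.057121	-0.016129	-0	-0.1296	-0.084681	-0.755161	-0.444889	-0.148996
S	-0.09	-0.519841	-0.028224	-0.1089	-0.1764	-0.160801	-0.004225	-0.262144	-0.1849	-0.262144	-0.160801	-0.032761	-0.014641	-0.054289	-0.1296	-0	-0.004761	-0.259081	-0.094249	-0.000676
T	-0.136161	-0.6241	-0.009801	-0.068121	-0.239121	-0.2209	-1.6e-05	-0.337561	-0.130321	-0.337561	-0.2209	-0.012544	-0.002704	-0.026896	-0.084681	-0.004761	-0	-0.334084	-0.141376	-0.009025
V	-0.043681	-0.044944	-0.458329	-0.703921	-0.007921	-0.011664	-0.329476	-9e-06	-0.881721	-9e-06	-0.011664	-0.4761	-0.3969	-0.550564	-0.755161	-0.259081	-0.334084	-0	-0.040804	-0.233289
W	-4.9e-05	-0.171396	-0.225625	-0.405769	-0.012769	-0.008836	-0.138384	-0.042025	-0.543169	-0.042025	-0.008836	-0.238144	-0.183184	-0.2916	-0.444889	-0.094249	-0.141376	-0.040804	-0	-0.078961
Y	-0.075076	-0.483025	-0.037636	-0.126736	-0.155236	-0.140625	-0.008281	-0.236196	-0.207936	-0.236196	-0.140625	-0.042849	-0.021609	-0.067081	-0.148996	-0.000676	-0.009025	-0.233289	-0.078961	-0
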