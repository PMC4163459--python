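wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.006084	-0.007056	-0.0121	-0.004761	-0.002209	-0.001156	-0.003249	-0.013924	-0.002401	-0.001024	-0.004096	-0.004225	-0.002809	-0.000576	-0.003844	-0.000169	-0.002809	-0.0064	-0.003025
C	-0.006084	-0	-0.026244	-0.035344	-8.1e-05	-0.015625	-0.001936	-0.000441	-0.038416	-0.000841	-0.002116	-0.020164	-0.020449	-0.017161	-0.010404	-0.0196	-0.008281	-0.000625	-4e-06	-0.000529
D	-0.007056	-0.026244	-0	-0.000676	-0.023409	-0.001369	-0.013924	-0.019881	-0.001156	-0.017689	-0.013456	-0.0004	-0.000361	-0.000961	-0.0036	-0.000484	-0.005041	-0.018769	-0.026896	-0.019321
E	-0.0121	-0.035344	-0.000676	-0	-0.032041	-0.003969	-0.020736	-0.027889	-6.4e-05	-0.025281	-0.020164	-0.002116	-0.002025	-0.003249	-0.007396	-0.002304	-0.009409	-0.026569	-0.0361	-0.027225
F	-0.004761	-8.1e-05	-0.023409	-0.032041	-0	-0.013456	-0.001225	-0.000144	-0.034969	-0.0004	-0.001369	-0.017689	-0.017956	-0.014884	-0.008649	-0.017161	-0.006724	-0.000256	-0.000121	-0.000196
G	-0.002209	-0.015625	-0.001369	-0.003969	-0.013456	-0	-0.006561	-0.010816	-0.005041	-0.009216	-0.006241	-0.000289	-0.000324	-3.6e-05	-0.000529	-0.000225	-0.001156	-0.01	-0.016129	-0.010404
H	-0.001156	-0.001936	-0.013924	-0.020736	-0.001225	-0.006561	-0	-0.000529	-0.023104	-0.000225	-4e-06	-0.009604	-0.009801	-0.007569	-0.003364	-0.009216	-0.002209	-0.000361	-0.002116	-0.000441
I	-0.003249	-0.000441	-0.019881	-0.027889	-0.000144	-0.010816	-0.000529	-0	-0.030625	-6.4e-05	-0.000625	-0.014641	-0.014884	-0.0121	-0.006561	-0.014161	-0.0049	-1.6e-05	-0.000529	-4e-06
K	-0.013924	-0.038416	-0.001156	-6.4e-05	-0.034969	-0.005041	-0.023104	-0.030625	-0	-0.027889	-0.0225	-0.002916	-0.002809	-0.004225	-0.008836	-0.003136	-0.011025	-0.029241	-0.039204	-0.029929
L	-0.002401	-0.000841	-0.017689	-0.025281	-0.0004	-0.009216	-0.000225	-6.4e-05	-0.027889	-0	-0.000289	-0.012769	-0.012996	-0.010404	-0.005329	-0.012321	-0.003844	-1.6e-05	-0.000961	-3.6e-05
M	-0.001024	-0.002116	-0.013456	-0.020164	-0.001369	-0.006241	-4e-06	-0.000625	-0.0225	-0.000289	-0	-0.009216	-0.009409	-0.007225	-0.003136	-0.008836	-0.002025	-0.000441	-0.002304	-0.000529
N	-0.004096	-0.020164	-0.0004	-0.002116	-0.017689	-0.000289	-0.009604	-0.014641	-0.002916	-0.012769	-0.009216	-0	-1e-06	-0.000121	-0.0016	-4e-06	-0.002601	-0.013689	-0.020736	-0.014161
P	-0.004225	-0.020449	-0.000361	-0.002025	-0.017956	-0.000324	-0.009801	-0.014884	-0.002809	-0.012996	-0.009409	-1e-06	-0	-0.000144	-0.001681	-9e-06	-0.002704	-0.013924	-0.021025	-0.0144
Q	-0.002809	-0.017161	-0.000961	-0.003249	-0.014884	-3.6e-05	-0.007569	-0.0121	-0.004225	-0.010404	-0.007225	-0.000121	-0.000144	-0	-0.000841	-8.1e-05	-0.0016	-0.011236	-0.017689	-0.011664
R	-0.000576	-0.010404	-0.0036	-0.007396	-0.008649	-0.000529	-0.003364	-0.006561	-0.008836	-0.005329	-0.003136	-0.0016	-0.001681	-0.000841	-0	-0.001444	-0.000121	-0.005929	-0.010816	-0.006241
S	-0.003844	-0.0196	-0.000484	-0.002304	-0.017161	-0.000225	-0.009216	-0.014161	-0.003136	-0.012321	-0.008836	-4e-06	-9e-06	-8.1e-05	-0.001444	-0	-0.002401	-0.013225	-0.020164	-0.013689
T	-0.000169	-0.008281	-0.005041	-0.009409	-0.006724	-0.001156	-0.002209	-0.0049	-0.011025	-0.003844	-0.002025	-0.002601	-0.002704	-0.0016	-0.000121	-0.002401	-0	-0.004356	-0.008649	-0.004624
V	-0.002809	-0.000625	-0.018769	-0.026569	-0.000256	-0.01	-0.000361	-1.6e-05	-0.029241	-1.6e-05	-0.000441	-0.013689	-0.013924	-0.011236	-0.005929	-0.013225	-0.004356	-0	-0.000729	-4e-06
W	-0.0064	-4e-06	-0.026896	-0.0361	-0.000121	-0.016129	-0.002116	-0.000529	-0.039204	-0.000961	-0.002304	-0.020736	-0.021025	-0.017689	-0.010816	-0.020164	-0.008649	-0.000729	-0	-0.000625
Y	-0.003025	-0.000529	-0.019321	-0.027225	-0.000196	-0.010404	-0.000441	-4e-06	-0.029929	-3.6e-05	-0.000529	-0.014161	-0.0144	-0.011664	-0.006241	-0.013689	-0.004624	-4e-06	-0.000625	-0
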