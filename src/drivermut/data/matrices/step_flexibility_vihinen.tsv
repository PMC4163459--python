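wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-0.078	-0.084	-0.11	-0.069	-0.047	-0.034	-0.057	-0.118	-0.049	-0.032	-0.064	-0.065	-0.053	-0.024	-0.062	-0.013	-0.053	-0.08	-0.055
C	-0.078	-0	-0.162	-0.188	-0.009	-0.125	-0.044	-0.021	-0.196	-0.029	-0.046	-0.142	-0.143	-0.131	-0.102	-0.14	-0.091	-0.025	-0.002	-0.023
D	-0.084	-0.162	-0	-0.026	-0.153	-0.037	-0.118	-0.141	-0.034	-0.133	-0.116	-0.02	-0.019	-0.031	-0.06	-0.022	-0.071	-0.137	-0.164	-0.139
E	-0.11	-0.188	-0.026	-0	-0.179	-0.063	-0.144	-0.167	-0.008	-0.159	-0.142	-0.046	-0.045	-0.057	-0.086	-0.048	-0.097	-0.163	-0.19	-0.165
F	-0.069	-0.009	-0.153	-0.179	-0	-0.116	-0.035	-0.012	-0.187	-0.02	-0.037	-0.133	-0.134	-0.122	-0.093	-0.131	-0.082	-0.016	-0.011	-0.014
G	-0.047	-0.125	-0.037	-0.063	-0.116	-0	-0.081	-0.104	-0.071	-0.096	-0.079	-0.017	-0.018	-0.006	-0.023	-0.015	-0.034	-0.1	-0.127	-0.102
H	-0.034	-0.044	-0.118	-0.144	-0.035	-0.081	-0	-0.023	-0.152	-0.015	-0.002	-0.098	-0.099	-0.087	-0.058	-0.096	-0.047	-0.019	-0.046	-0.021
I	-0.057	-0.021	-0.141	-0.167	-0.012	-0.104	-0.023	-0	-0.175	-0.008	-0.025	-0.121	-0.122	-0.11	-0.081	-0.119	-0.07	-0.004	-0.023	-0.002
K	-0.118	-0.196	-0.034	-0.008	-0.187	-0.071	-0.152	-0.175	-0	-0.167	-0.15	-0.054	-0.053	-0.065	-0.094	-0.056	-0.105	-0.171	-0.198	-0.173
L	-0.049	-0.029	-0.133	-0.159	-0.02	-0.096	-0.015	-0.008	-0.167	-0	-0.017	-0.113	-0.114	-0.102	-0.073	-0.111	-0.062	-0.004	-0.031	-0.006
M	-0.032	-0.046	-0.116	-0.142	-0.037	-0.079	-0.002	-0.025	-0.15	-0.017	-0	-0.096	-0.097	-0.085	-0.056	-0.094	-0.045	-0.021	-0.048	-0.023
N	-0.064	-0.142	-0.02	-0.046	-0.133	-0.017	-0.098	-0.121	-0.054	-0.113	-0.096	-0	-0.001	-0.011	-0.04	-0.002	-0.051	-0.117	-0.144	-0.119
P	-0.065	-0.143	-0.019	-0.045	-0.134	-0.018	-0.099	-0.122	-0.053	-0.114	-0.097	-0.001	-0	-0.012	-0.041	-0.003	-0.052	-0.118	-0.145	-0.12
Q	-0.053	-0.131	-0.031	-0.057	-0.122	-0.006	-0.087	-0.11	-0.065	-0.102	-0.085	-0.011	-0.012	-0	-0.029	-0.009	-0.04	-0.106	-0.133	-0.108
R	-0.024	-0.102	-0.06	-0.086	-0.093	-0.023	-0.058	-0.081	-0.094	-0.073	-0.056	-0.04	-0.041	-0.029	-0	-0.038	-0.011	-0.077	-0.104	-0.079
S	-0.062	-0.14	-0.022	-0.048	-0.131	-0.015	-0.096	-0.119	-0.056	-0.111	-0.094	-0.002	-0.003	-0.009	-0.038	-0	-0.049	-0.115	-0.142	-0.117
T	-0.013	-0.091	-0.071	-0.097	-0.082	-0.034	-0.047	-0.07	-0.105	-0.062	-0.045	-0.051	-0.052	-0.04	-0.011	-0.049	-0	-0.066	-0.093	-0.068
V	-0.053	-0.025	-0.137	-0.163	-0.016	-0.1	-0.019	-0.004	-0.171	-0.004	-0.021	-0.117	-0.118	-0.106	-0.077	-0.115	-0.066	-0	-0.027	-0.002
W	-0.08	-0.002	-0.164	-0.19	-0.011	-0.127	-0.046	-0.023	-0.198	-0.031	-0.048	-0.144	-0.145	-0.133	-0.104	-0.142	-0.093	-0.027	-0	-0.025
Y	-0.055	-0.023	-0.139	-0.165	-0.014	-0.102	-0.021	-0.002	-0.173	-0.006	-0.023	-0.119	-0.12	-0.108	-0.079	-0.117	-0.068	-0.002	-0.025	-0
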