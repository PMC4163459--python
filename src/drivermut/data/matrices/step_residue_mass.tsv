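wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-32.065	-44.0095	-58.0361	-76.0959	-14.0266	-66.0614	-42.0797	-57.0944	-42.0797	-60.1181	-43.0247	-26.0373	-57.0513	-85.1078	-15.9994	-30.026	-28.0531	-115.132	-92.0953
C	-32.065	-0	-11.9445	-25.9711	-44.0309	-46.0916	-33.9964	-10.0147	-25.0294	-10.0147	-28.0531	-10.9597	-6.0277	-24.9863	-53.0428	-16.0656	-2.039	-4.0119	-83.067	-60.0303
D	-44.0095	-11.9445	-0	-14.0266	-32.0864	-58.0361	-22.0519	-1.9298	-13.0849	-1.9298	-16.1086	-0.9848	-17.9722	-13.0418	-41.0983	-28.0101	-13.9835	-15.9564	-71.1225	-48.0858
E	-58.0361	-25.9711	-14.0266	-0	-18.0598	-72.0627	-8.0253	-15.9564	-0.9417	-15.9564	-2.082	-15.0114	-31.9988	-0.9848	-27.0717	-42.0367	-28.0101	-29.983	-57.0959	-34.0592
F	-76.0959	-44.0309	-32.0864	-18.0598	-0	-90.1225	-10.0345	-34.0162	-19.0015	-34.0162	-15.9778	-33.0712	-50.0586	-19.0446	-9.0119	-60.0965	-46.0699	-48.0428	-39.0361	-15.9994
G	-14.0266	-46.0916	-58.0361	-72.0627	-90.1225	-0	-80.088	-56.1063	-71.121	-56.1063	-74.1447	-57.0513	-40.0639	-71.0779	-99.1344	-30.026	-44.0526	-42.0797	-129.159	-106.122
H	-66.0614	-33.9964	-22.0519	-8.0253	-10.0345	-80.088	-0	-23.9817	-8.967	-23.9817	-5.9433	-23.0367	-40.0241	-9.0101	-19.0464	-50.062	-36.0354	-38.0083	-49.0706	-26.0339
I	-42.0797	-10.0147	-1.9298	-15.9564	-34.0162	-56.1063	-23.9817	-0	-15.0147	-0	-18.0384	-0.945	-16.0424	-14.9716	-43.0281	-26.0803	-12.0537	-14.0266	-73.0523	-50.0156
K	-57.0944	-25.0294	-13.0849	-0.9417	-19.0015	-71.121	-8.967	-15.0147	-0	-15.0147	-3.0237	-14.0697	-31.0571	-0.0431	-28.0134	-41.095	-27.0684	-29.0413	-58.0376	-35.0009
L	-42.0797	-10.0147	-1.9298	-15.9564	-34.0162	-56.1063	-23.9817	-0	-15.0147	-0	-18.0384	-0.945	-16.0424	-14.9716	-43.0281	-26.0803	-12.0537	-14.0266	-73.0523	-50.0156
M	-60.1181	-28.0531	-16.1086	-2.082	-15.9778	-74.1447	-5.9433	-18.0384	-3.0237	-18.0384	-0	-17.0934	-34.0808	-3.0668	-24.9897	-44.1187	-30.0921	-32.065	-55.0139	-31.9772
N	-43.0247	-10.9597	-0.9848	-15.0114	-33.0712	-57.0513	-23.0367	-0.945	-14.0697	-0.945	-17.0934	-0	-16.9874	-14.0266	-42.0831	-27.0253	-12.9987	-14.9716	-72.1073	-49.0706
P	-26.0373	-6.0277	-17.9722	-31.9988	-50.0586	-40.0639	-40.0241	-16.0424	-31.0571	-16.0424	-34.0808	-16.9874	-0	-31.014	-59.0705	-10.0379	-3.9887	-2.0158	-89.0947	-66.058
Q	-57.0513	-24.9863	-13.0418	-0.9848	-19.0446	-71.0779	-9.0101	-14.9716	-0.0431	-14.9716	-3.0668	-14.0266	-31.014	-0	-28.0565	-41.0519	-27.0253	-28.9982	-58.0807	-35.044
R	-85.1078	-53.0428	-41.0983	-27.0717	-9.0119	-99.1344	-19.0464	-43.0281	-28.0134	-43.0281	-24.9897	-42.0831	-59.0705	-28.0565	-0	-69.1084	-55.0818	-57.0547	-30.0242	-6.9875
S	-15.9994	-16.0656	-28.0101	-42.0367	-60.0965	-30.026	-50.062	-26.0803	-41.095	-26.0803	-44.1187	-27.0253	-10.0379	-41.0519	-69.1084	-0	-14.0266	-12.0537	-99.1326	-76.0959
T	-30.026	-2.039	-13.9835	-28.0101	-46.0699	-44.0526	-36.0354	-12.0537	-27.0684	-12.0537	-30.0921	-12.9987	-3.9887	-27.0253	-55.0818	-14.0266	-0	-1.9729	-85.106	-62.0693
V	-28.0531	-4.0119	-15.9564	-29.983	-48.0428	-42.0797	-38.0083	-14.0266	-29.0413	-14.0266	-32.065	-14.9716	-2.0158	-28.9982	-57.0547	-12.0537	-1.9729	-0	-87.0789	-64.0422
W	-115.132	-83.067	-71.1225	-57.0959	-39.0361	-129.159	-49.0706	-73.0523	-58.0376	-73.0523	-55.0139	-72.1073	-89.0947	-58.0807	-30.0242	-99.1326	-85.106	-87.0789	-0	-23.0367
Y	-92.0953	-60.0303	-48.0858	-34.0592	-15.9994	-106.122	-26.0339	-50.0156	-35.0009	-50.0156	-31.9772	-49.0706	-66.058	-35.044	-6.9875	-76.0959	-62.0693	-64.0422	-23.0367	-0
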