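wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-576	-529	-2704	-10201	-784	-4225	-6400	-7744	-6400	-5476	-625	-2.25	-2916	-8649	-1	-900	-2809	-19321	-11025
C	-576	-0	-1	-784	-5929	-2704	-1681	-3136	-4096	-3136	-2500	-1	-506.25	-900	-4761	-529	-36	-841	-13225	-6561
D	-529	-1	-0	-841	-6084	-2601	-1764	-3249	-4225	-3249	-2601	-4	-462.25	-961	-4900	-484	-49	-900	-13456	-6724
E	-2704	-784	-841	-0	-2401	-6400	-169	-784	-1296	-784	-484	-729	-2550.25	-4	-1681	-2601	-484	-1	-7569	-2809
F	-10201	-5929	-6084	-2401	-0	-16641	-1296	-441	-169	-441	-729	-5776	-9900.25	-2209	-64	-10000	-5041	-2304	-1444	-16
G	-784	-2704	-2601	-6400	-16641	-0	-8649	-11664	-13456	-11664	-10404	-2809	-870.25	-6724	-14641	-841	-3364	-6561	-27889	-17689
H	-4225	-1681	-1764	-169	-1296	-8649	-0	-225	-529	-225	-81	-1600	-4032.25	-121	-784	-4096	-1225	-144	-5476	-1600
I	-6400	-3136	-3249	-784	-441	-11664	-225	-0	-64	-0	-36	-3025	-6162.25	-676	-169	-6241	-2500	-729	-3481	-625
K	-7744	-4096	-4225	-1296	-169	-13456	-529	-64	-0	-64	-196	-3969	-7482.25	-1156	-25	-7569	-3364	-1225	-2601	-289
L	-6400	-3136	-3249	-784	-441	-11664	-225	-0	-64	-0	-36	-3025	-6162.25	-676	-169	-6241	-2500	-729	-3481	-625
M	-5476	-2500	-2601	-484	-729	-10404	-81	-36	-196	-36	-0	-2401	-5256.25	-400	-361	-5329	-1936	-441	-4225	-961
N	-625	-1	-4	-729	-5776	-2809	-1600	-3025	-3969	-3025	-2401	-0	-552.25	-841	-4624	-576	-25	-784	-12996	-6400
P	-2.25	-506.25	-462.25	-2550.25	-9900.25	-870.25	-4032.25	-6162.25	-7482.25	-6162.25	-5256.25	-552.25	-0	-2756.25	-8372.25	-0.25	-812.25	-2652.25	-18906.2	-10712.2
Q	-2916	-900	-961	-4	-2209	-6724	-121	-676	-1156	-676	-400	-841	-2756.25	-0	-1521	-2809	-576	-1	-7225	-2601
R	-8649	-4761	-4900	-1681	-64	-14641	-784	-169	-25	-169	-361	-4624	-8372.25	-1521	-0	-8464	-3969	-1600	-2116	-144
S	-1	-529	-484	-2601	-10000	-841	-4096	-6241	-7569	-6241	-5329	-576	-0.25	-2809	-8464	-0	-841	-2704	-19044	-10816
T	-900	-36	-49	-484	-5041	-3364	-1225	-2500	-3364	-2500	-1936	-25	-812.25	-576	-3969	-841	-0	-529	-11881	-5625
V	-2809	-841	-900	-1	-2304	-6561	-144	-729	-1225	-729	-441	-784	-2652.25	-1	-1600	-2704	-529	-0	-7396	-2704
W	-19321	-13225	-13456	-7569	-1444	-27889	-5476	-3481	-2601	-3481	-4225	-12996	-18906.2	-7225	-2116	-19044	-11881	-7396	-0	-1156
Y	-11025	-6561	-6724	-2809	-16	-17689	-1600	-625	-289	-625	-961	-6400	-10712.2	-2601	-144	-10816	-5625	-2704	-1156	-0
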