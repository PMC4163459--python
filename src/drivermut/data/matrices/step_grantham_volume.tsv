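wild	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0	-24	-23	-52	-101	-28	-65	-80	-88	-80	-74	-25	-1.5	-54	-93	-1	-30	-53	-139	-105
C	-24	-0	-1	-28	-77	-52	-41	-56	-64	-56	-50	-1	-22.5	-30	-69	-23	-6	-29	-115	-81
D	-23	-1	-0	-29	-78	-51	-42	-57	-65	-57	-51	-2	-21.5	-31	-70	-22	-7	-30	-116	-82
E	-52	-28	-29	-0	-49	-80	-13	-28	-36	-28	-22	-27	-50.5	-2	-41	-51	-22	-1	-87	-53
F	-101	-77	-78	-49	-0	-129	-36	-21	-13	-21	-27	-76	-99.5	-47	-8	-100	-71	-48	-38	-4
G	-28	-52	-51	-80	-129	-0	-93	-108	-116	-108	-102	-53	-29.5	-82	-121	-29	-58	-81	-167	-133
H	-65	-41	-42	-13	-36	-93	-0	-15	-23	-15	-9	-40	-63.5	-11	-28	-64	-35	-12	-74	-40
I	-80	-56	-57	-28	-21	-108	-15	-0	-8	-0	-6	-55	-78.5	-26	-13	-79	-50	-27	-59	-25
K	-88	-64	-65	-36	-13	-116	-23	-8	-0	-8	-14	-63	-86.5	-34	-5	-87	-58	-35	-51	-17
L	-80	-56	-57	-28	-21	-108	-15	-0	-8	-0	-6	-55	-78.5	-26	-13	-79	-50	-27	-59	-25
M	-74	-50	-51	-22	-27	-102	-9	-6	-14	-6	-0	-49	-72.5	-20	-19	-73	-44	-21	-65	-31
N	-25	-1	-2	-27	-76	-53	-40	-55	-63	-55	-49	-0	-23.5	-29	-68	-24	-5	-28	-114	-80
P	-1.5	-22.5	-21.5	-50.5	-99.5	-29.5	-63.5	-78.5	-86.5	-78.5	-72.5	-23.5	-0	-52.5	-91.5	-0.5	-28.5	-51.5	-137.5	-103.5
Q	-54	-30	-31	-2	-47	-82	-11	-26	-34	-26	-20	-29	-52.5	-0	-39	-53	-24	-1	-85	-51
R	-93	-69	-70	-41	-8	-121	-28	-13	-5	-13	-19	-68	-91.5	-39	-0	-92	-63	-40	-46	-12
S	-1	-23	-22	-51	-100	-29	-64	-79	-87	-79	-73	-24	-0.5	-53	-92	-0	-29	-52	-138	-104
T	-30	-6	-7	-22	-71	-58	-35	-50	-58	-50	-44	-5	-28.5	-24	-63	-29	-0	-23	-109	-75
V	-53	-29	-30	-1	-48	-81	-12	-27	-35	-27	-21	-28	-51.5	-1	-40	-52	-23	-0	-86	-52
W	-139	-115	-116	-87	-38	-167	-74	-59	-51	-59	-65	-114	-137.5	-85	-46	-138	-109	-86	-0	-34
Y	-105	-81	-82	-53	-4	-133	-40	-25	-17	-25	-31	-80	-103.5	-51	-12	-104	-75	-52	-34	-0
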