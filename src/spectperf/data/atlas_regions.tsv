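region_id	name	hemisphere	group	is_gray
1	STG	left	temporal	True
2	STG	right	temporal	True
3	MTG	left	temporal	True
4	MTG	right	temporal	True
5	ITG	left	temporal	True
6	ITG	right	temporal	True
7	A	left	limbic	True
8	A	right	limbic	True
9	H	left	limbic	True
10	H	right	limbic	True
11	PHG	left	limbic	True
12	PHG	right	limbic	True
13	CingG	left	limbic	True
14	CingG	right	limbic	True
15	Entor	left	limbic	True
16	Entor	right	limbic	True
17	Insul	left	limbic	True
18	Insul	right	limbic	True
19	SFG	left	frontal	True
20	SFG	right	frontal	True
21	MFG	left	frontal	True
22	MFG	right	frontal	True
23	IFG	left	frontal	True
24	IFG	right	frontal	True
25	PrecG	left	frontal	True
26	PrecG	right	frontal	True
27	MOFG	left	frontal	True
28	MOFG	right	frontal	True
29	LOFG	left	frontal	True
30	LOFG	right	frontal	True
31	STRAG	left	frontal	True
32	STRAG	right	frontal	True
33	SPG	left	parietal	True
34	SPG	right	parietal	True
35	PostG	left	parietal	True
36	PostG	right	parietal	True
37	AG	left	parietal	True
38	AG	right	parietal	True
39	Supram	left	parietal	True
40	Supram	right	parietal	True
41	Precuneus	left	parietal	True
42	Precuneus	right	parietal	True
43	Cuneus	left	occipital	True
44	Cuneus	right	occipital	True
45	LingG	left	occipital	True
46	LingG	right	occipital	True
47	SOG	left	occipital	True
48	SOG	right	occipital	True
49	FusifG	left	temporal	True
50	FusifG	right	temporal	True
51	IOG	left	occipital	True
52	IOG	right	occipital	True
53	MOG	left	occipital	True
54	MOG	right	occipital	True
55	CN	left	subcortical	True
56	CN	right	subcortical	True
57	P	left	subcortical	True
58	P	right	subcortical	True
59	T	left	subcortical	True
60	T	right	subcortical	True
61	GP	left	subcortical	True
62	GP	right	subcortical	True
63	RedN	left	brainstem	True
64	RedN	right	brainstem	True
65	SNig	left	brainstem	True
66	SNig	right	brainstem	True
67	M	left	brainstem	True
68	M	right	brainstem	True
69	MO	left	brainstem	True
70	MO	right	brainstem	True
71	Pons	left	brainstem	True
72	Pons	right	brainstem	True
73	Cerebellum	left	cerebellum	True
74	Cerebellum	right	cerebellum	True
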