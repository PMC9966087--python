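specimen_no	repository_id	epoch	provenance	included_in_analysis	body_length_mm	length_is_estimate	labrum_morphotype	notes
1		extant	prior_study	true		false	unknown	
2		extant	prior_study	true		false	unknown	
3		extant	prior_study	true		false	unknown	
4		extant	prior_study	true		false	unknown	
5		extant	prior_study	true		false	unknown	
6		extant	prior_study	true		false	unknown	
7		extant	prior_study	true		false	unknown	
8		extant	prior_study	true		false	unknown	
9		extant	prior_study	true		false	unknown	
10		extant	prior_study	true		false	unknown	
11		extant	prior_study	true		false	unknown	
12		extant	prior_study	true		false	unknown	
13		Eocene	prior_study	true		false	unknown	
14		Eocene	prior_study	true		false	unknown	
15		Eocene	prior_study	true		false	unknown	
16		Eocene	prior_study	true		false	unknown	
17		Eocene	prior_study	true		false	unknown	
18		Eocene	prior_study	true		false	unknown	
19		Eocene	prior_study	true		false	unknown	
20		Eocene	prior_study	true		false	unknown	
21		Eocene	prior_study	true		false	unknown	
22		Eocene	prior_study	true		false	unknown	
23		Eocene	prior_study	true		false	unknown	
24		Eocene	prior_study	true		false	unknown	
25		Cretaceous	prior_study	true		false	unknown	
26		Cretaceous	prior_study	true		false	unknown	
27		Cretaceous	prior_study	true		false	unknown	
28		Cretaceous	prior_study	true		false	unknown	
29		Cretaceous	prior_study	true		false	unknown	
30		Cretaceous	prior_study	true		false	unknown	
31		Cretaceous	prior_study	true		false	unknown	
32		Cretaceous	prior_study	true		false	unknown	
33		Cretaceous	prior_study	true		false	unknown	
34		Cretaceous	prior_study	true		false	unknown	
35		Cretaceous	prior_study	true		false	unknown	
36		Cretaceous	prior_study	true		false	unknown	
37		Cretaceous	prior_study	true		false	unknown	
38		Cretaceous	prior_study	true		false	unknown	
39		Cretaceous	prior_study	true		false	unknown	
40		Cretaceous	prior_study	true		false	unknown	
41		Cretaceous	prior_study	true		false	unknown	
42		Cretaceous	prior_study	true		false	unknown	
43		Cretaceous	prior_study	true		false	unknown	
44		Cretaceous	prior_study	true		false	unknown	
45		Cretaceous	prior_study	true		false	unknown	
46		Cretaceous	prior_study	true		false	unknown	
47		Cretaceous	prior_study	true		false	unknown	
48		Cretaceous	prior_study	true		false	unknown	
49		Cretaceous	prior_study	true		false	unknown	
50		Cretaceous	prior_study	true		false	unknown	
51		Cretaceous	prior_study	true		false	unknown	
52		Cretaceous	prior_study	true		false	unknown	
53	PED 0150	Cretaceous	this_study	false	3.6	false	unknown	labrum partly concealed; head turned or deformed
54	PED 0267	Cretaceous	this_study	false	14	true	unknown	only head capsule present, rim and labrum concealed
55	PED 0322	Cretaceous	this_study	false	3.9	false	triangular	head accessible only laterally
56	PED 0379	Cretaceous	this_study	true	5.5	false	pentadent	trident-like with five prongs
57	PED 0382	Cretaceous	this_study	true	8.6	false	trident	
58	PED 0389	Cretaceous	this_study	true	9.9	false	trident	
59	PED 0412	Cretaceous	this_study	true	2.8	false	broad	broad pentagonal labrum with spine-like corner elevations
60	PED 0430	Cretaceous	this_study	true	3.6	false	trident_bifid	large bifurcated middle spine
61	PED 0440	Cretaceous	this_study	true	1.2	false	unknown	labrum triangular to pentagonal
62	PED 0456	Cretaceous	this_study	true	1.5	false	unknown	trapezoidal labrum with large V-shaped distal split
63	PED 0535	Cretaceous	this_study	true	1.8	false	triangular	
64	PED 0584	Cretaceous	this_study	false	3.3	true	unknown	printed range 3.1-3.5 mm; triangular to pentagonal
65	PED 0612	Cretaceous	this_study	true	6.9	false	trident	
66	PED 0621	Cretaceous	this_study	true	5.7	false	trident	
67	PED 0625	Cretaceous	this_study	false	14.1	true	trident	printed range 12.4-15.8 mm; head only, partly ground off
68	PED 0662	Cretaceous	this_study	true	8.3	false	broad	labrum relatively broad and short
69	PED 0751	Cretaceous	this_study	true	9.85	true	trident	measured ~5.0 mm; printed estimate 9.2-10.5 mm
70	PED 0774	Cretaceous	this_study	true	2.6	true	triangular	printed range 2.5-2.7 mm
71	PED 0845	Cretaceous	this_study	false	15.7	false	unknown	labrum shape not discernible
72	PED 0932	Cretaceous	this_study	true	5.65	true	trident_bifid	printed range 5.4-5.9 mm
73	PED 0998	Cretaceous	this_study	true	10.5	false	triangular	triangular with shallow distal cleft
74	PED 1049	Cretaceous	this_study	true	7.6	true	trident	printed range 7.2-8.0 mm; head and neck only
75	PED 1459	Cretaceous	this_study	true	2	false	triangular	
76	PED 1627	Cretaceous	this_study	true	10.1	false	pentagonal	labrum broad, short, pentagonal
77	PED 1666	Cretaceous	this_study	true	1.9	false	unknown	labrum triangular to pentagonal; fan-like setae
78	PED 1703	Cretaceous	this_study	true	2.9	false	pentagonal	pentagonal, well rounded
79	PED 1726	Cretaceous	this_study	true	10.6	true	broad	measured ~7.6 mm; printed estimate 10.4-10.8 mm; broad short labrum with broad cleft
80	PED 1732	Cretaceous	this_study	true	7.7	false	broad	broad pentagonal labrum with spine-like corner elevations
81	PED 1813	Cretaceous	this_study	true	3.5	false	broad	almost square labrum, middle cleft and two flanking clefts
82	PED 1831	Cretaceous	this_study	true	3.25	true	triangular	printed range 3.0-3.5 mm; head and neck only
83	PED 1846	Cretaceous	this_study	true	4.1	true	broad	printed range 3.9-4.3 mm; almost square labrum with clefts
84	PED 1884	Cretaceous	this_study	true	3.4	false	trident_bifid	bifurcated middle spine longer than in known larvae
85	PED 1887	Cretaceous	this_study	false	4.5	true	broad	head separated from body, neck region missing
86	PED 1928	Cretaceous	this_study	true	6.2	true	trident_bifid	measured ~4.0 mm; printed estimate 5.6-6.8 mm
87	PED 1940	Cretaceous	this_study	true	2.55	true	triangular	measured ~1.3 mm; printed estimate 2.3-2.8 mm
88	PED 1967	Cretaceous	this_study	true	11.9	false	trident	
89	PED 2056	Cretaceous	this_study	true	4.1	false	triangular	triangular symmetric to trapezium-like, elongated
90	PED 2171	Cretaceous	this_study	true	2.6	false	triangular	triangular symmetric to trapezium-like, elongated
91	PED 2309	Cretaceous	this_study	true	2.2	false	triangular	triangular symmetric to trapezium-like, elongated
92	PED 2311	Cretaceous	this_study	true	1.3	false	triangular	triangular symmetric to trapezium-like, very elongated
93	PED 2329	Cretaceous	this_study	true	1.8	false	pentagonal	pentagonal, relatively broad; head only
94	PED 2446	Cretaceous	this_study	true	2	false	triangular	triangular, relatively elongated; head only
95	PED 2448	Cretaceous	this_study	false	5	true	unknown	only rough outline apparent
96	PED 2432	Cretaceous	this_study	true	8.5	false	unknown	labrum simple triangular to pentagonal
97		Eocene	this_study	false	3	true	unknown	known only from Ross's small published photograph, bubble conceals part of body; assumed excluded (head-based analyses uncertain)
98		Eocene	this_study	true		false	unknown	high-quality photographs provided by M. Veta; assumed included for head-based analyses
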