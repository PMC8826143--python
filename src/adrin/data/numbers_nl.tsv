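0	nul
1	een
2	twee
3	drie
4	vier
5	vijf
6	zes
7	zeven
8	acht
9	negen
10	tien
11	elf
12	twaalf
13	dertien
14	veertien
15	vijftien
16	zestien
17	zeventien
18	achttien
19	negentien
20	twintig
21	eenentwintig
22	tweeentwintig
23	drieentwintig
24	vierentwintig
25	vijfentwintig
26	zesentwintig
27	zevenentwintig
28	achtentwintig
29	negenentwintig
30	dertig
31	eenendertig
32	tweeendertig
33	drieendertig
34	vierendertig
35	vijfendertig
36	zesendertig
37	zevenendertig
38	achtendertig
39	negenendertig
40	veertig
41	eenenveertig
42	tweeenveertig
43	drieenveertig
44	vierenveertig
45	vijfenveertig
46	zesenveertig
47	zevenenveertig
48	achtenveertig
49	negenenveertig
50	vijftig
51	eenenvijftig
52	tweeenvijftig
53	drieenvijftig
54	vierenvijftig
55	vijfenvijftig
56	zesenvijftig
57	zevenenvijftig
58	achtenvijftig
59	negenenvijftig
60	zestig
61	eenenzestig
62	tweeenzestig
63	drieenzestig
64	vierenzestig
65	vijfenzestig
66	zesenzestig
67	zevenenzestig
68	achtenzestig
69	negenenzestig
70	zeventig
71	eenenzeventig
72	tweeenzeventig
73	drieenzeventig
74	vierenzeventig
75	vijfenzeventig
76	zesenzeventig
77	zevenenzeventig
78	achtenzeventig
79	negenenzeventig
80	tachtig
81	eenentachtig
82	tweeentachtig
83	drieentachtig
84	vierentachtig
85	vijfentachtig
86	zesentachtig
87	zevenentachtig
88	achtentachtig
89	negenentachtig
90	negentig
91	eenennegentig
92	tweeennegentig
93	drieennegentig
94	vierennegentig
95	vijfennegentig
96	zesennegentig
97	zevenennegentig
98	achtennegentig
99	negenennegentig
100	honderd
200	tweehonderd
300	driehonderd
400	vierhonderd
500	vijfhonderd
600	zeshonderd
700	zevenhonderd
800	achthonderd
900	negenhonderd
1000	duizend
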