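phylotype_no	origins	closest_hit	pct_identity
1	SS-W,SS-R	Vibrio halioticoli	83
2	SH-W,SH-R	Vibrio breoganii	65
3	SH-W,SH-R,SS-W	Vibrio sp. JCM19236	96
4	SH-W,SS-W	Vibrio sp. A9m	96
5	SH-W,SH-R	Vibrio sp. JCM 19236	60
6	SH-W,SH-R	Vibrio sp. J2-12	96
7	SH-W,SH-R	Vibrio hyugaensis	59
8	SH-W,SH-R	Vibrio sp. J2-29	93
9	SS-W,SS-R	Vibrio halioticoli	86
10	SH-R	Vibrio cyclitrophicus	99
11	SS-R	Vibrio halioticoli	56
12	SH-W,SH-R,SS-W	Vibrio halioticoli	99
13	SS-W,SS-R	Vibrio ezurae	68
14	SH-R	Vibrio cyclitrophicus	99
15	SS-W,SS-R	Vibrio ezurae	66
16	SH-W,SH-R	Vibrio sp.	96
17	SS-W,SS-R	Vibrio ezurae	92
18	SH-R	Vibrio cyclitrophicus	99
19	SH-R	Vibrio splendidus	95
20	SH-W,SS-W	Vibrio breoganii	92
21	SH-R,SS-W	Vibrio splendidus	99
22	SS-W,SS-R	Vibrio diazotrophicus	78
23	SS-W,SS-R	Vibrio sp. J2-26	58
24	SS-R	Vibrio hyugaensis	69
25	SS-R	Vibrio halioticoli	59
26	SS-R	Vibrio halioticoli	90
27	SS-W,SS-R	Vibrio halioticoli	92
28	SS-W,SS-R	Vibrio ezurae	69
29	SS-W	Agarivorans sp. L11	58
30	SH-R	Psychromonas sp. SP041	73
31	SS-W	Vibrio ezurae	71
32	SS-W	Vibrio breoganii	80
33	SH-R	Vibrio cyclitrophicus	70
34	SS-W,SS-R	Vibrio ezurae	67
35	SH-R	Vibrio variabilis	65
36	SH-R	Psychromonas sp. SP041	74
37	SH-W,SS-W	Agarivorans sp. L11	97
38	SH-W,SS-W	Vibrio sp. A9m	96
39	SS-W	Psychromonas sp. SP041	75
40	SH-W	Microbulbifer sp. 6532A	63
41	SH-R	Vibrio variabilis	63
42	SH-W,SH-R	Vibrio ezurae	58
43	SS-W,SS-R	Vibrio halioticoli	64
44	SH-R	Vibrio cyclitrophicus	77
45	SH-W,SH-R	Vibrio cyclitrophicus	70
46	SH-R	Psychromonas sp. SP041	92
47	SS-W	Vibrio halioticoli	93
48	SS-W	Vibrio breoganii	77
49	SH-W	Microbulbifer sp. 6532A	61
50	SH-W,SH-R	Vibrio splendidus	97
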