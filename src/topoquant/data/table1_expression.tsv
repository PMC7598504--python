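gene	pathway	fpkm_10mM	fpkm_0.8mM	printed_log2fc	q
argA	Arginine biosynthesis	1422	256	-2.48	<0.001
argB	Arginine biosynthesis	2500	739	-1.76	<0.001
argC	Arginine biosynthesis	2154	446	-2.27	<0.001
argD_2	Arginine biosynthesis	1990	521	-1.93	<0.001
argE	Arginine biosynthesis	789	355	-1.15	<0.001
argI	Arginine biosynthesis	5296	454	-3.54	<0.001
argG	Arginine biosynthesis	3559	1825	-0.96	<0.001
argH	Arginine biosynthesis	2533	894	-1.50	<0.001
speA	Putrescine biosynthesis	533	850	0.67	0.003
adi	Putrescine biosynthesis	13	11	-0.27	0.35
speB	Putrescine biosynthesis	246	487	0.99	<0.001
speC	Putrescine biosynthesis	42	77	0.89	<0.001
speF	Putrescine biosynthesis	10	8	-0.22	0.59
potF	Putrescine import	498	548	0.13	0.73
potG	Putrescine import	224	311	0.47	0.053
potH	Putrescine import	83	118	0.51	0.17
potI	Putrescine import	114	154	0.42	0.25
yeeF	Putrescine import	450	1210	1.42	<0.001
sapB	Putrescine export	60	70	0.22	0.85
sapC	Putrescine export	69	78	0.17	0.90
sapD	Putrescine export	101	126	0.31	0.64
sapF	Putrescine export	73	92	0.33	0.21
potE	Putrescine export	7	6	-0.16	0.85
speE	Putrescine degradation	238	662	1.47	<0.001
oat	Putrescine degradation	225	84	-1.42	<0.001
ydcW	Putrescine degradation	71	61	-0.21	0.51
topA	DNA topoisomerases	289	298	0.04	0.94
gyrA	DNA topoisomerases	377	674	0.84	<0.001
gyrB	DNA topoisomerases	364	499	0.45	0.081
topB	DNA topoisomerases	122	160	0.39	0.13
parC	DNA topoisomerases	126	186	0.56	0.012
parE	DNA topoisomerases	295	383	0.38	0.15
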