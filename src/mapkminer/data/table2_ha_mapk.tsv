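Name	Gene ID	Chr	Str	Start	End	PL	Exo	Int	Sl	pI	Mw
HaMPK6-1	HanXRQChr01g0023391	Ha1	-	130301686	130292965	359	6	5	-	5.85	41581.61
HaMPK16-1	HanXRQChr03g0071491	Ha3	-	77378137	77372246	564	10	9	-	9.17	64059.43
HaMPK7	HanXRQChr03g0074811	Ha3	+	102410161	102406169	353	3	2	-	7.62	40274.83
HaMPK23-1	HanXRQChr03g0081221	Ha3	+	129978443	129973452	453	15	14	-	9.65	50392.28
HaMPK23-3	HanXRQChr03g0081391	Ha3	+	130506162	130500013	423	16	15	-	8.91	47648.79
HaMPK22	HanXRQChr04g0108301	Ha4	-	77321727	77315970	432	18	17	-	5.46	49633.87
HaMPK11-1	HanXRQChr04g0121371	Ha4	+	158781451	158778221	358	6	5	M	6.42	41228.21
HaMPK3-1	HanXRQChr05g0133161	Ha5	+	21064225	21061089	358	6	5	-	5.68	41323.35
HaMPK8	HanXRQChr05g0143371	Ha5	-	116774638	116767923	505	11	10	-	6.8	57051.89
HaMPK2	HanXRQChr05g0151241	Ha5	-	169574750	169571609	349	3	2	-	6.54	40295.67
HaMPK11-2	HanXRQChr06g0167011	Ha6	-	7104659	7099870	359	6	5	M	6.25	41336.17
HaMPK4	HanXRQChr06g0170261	Ha6	+	16894292	16893100	157	2	1	M	8.36	17702.54
HaMPK13-1	HanXRQChr06g0175501	Ha6	-	34635251	34631528	363	7	6	-	5.22	41353.31
HaMPK9-1	HanXRQChr06g0183531	Ha6	+	90706107	90699312	478	11	10	-	6.53	54442.91
HaMPK23-4	HanXRQChr08g0226701	Ha8	+	84318787	84308381	442	18	17	-	9.52	49480.06
HaMPK15	HanXRQChr08g0227231	Ha8	+	87599490	87591577	501	11	10	-	8.53	57073.07
HaMPK3-2	HanXRQChr08g0229941	Ha8	-	101013127	101009864	358	6	5	-	5.58	41298.31
HaMPK13-2	HanXRQChr08g0230171	Ha8	-	102808229	102804252	362	6	5	-	5.85	41552.83
HaMPK14	HanXRQChr09g0243011	Ha9	+	34673154	34669292	362	3	2	-	5.57	41423.42
HaMPK16-2	HanXRQChr09g0248301	Ha9	+	76212398	76202758	559	10	9	-	9.07	63370.4
HaMPK1	HanXRQChr09g0269211	Ha9	-	185086347	185083825	361	3	2	-	6.64	41831.44
HaMPK19-2	HanXRQChr11g0330461	Ha11	+	43791321	43784989	574	9	8	-	9.33	65344.85
HaMPK6-2	HanXRQChr11g0343001	Ha11	-	125967866	125963374	359	6	5	-	5.8	41553.72
HaMPK19-1	HanXRQChr13g0389781	Ha13	-	19048315	19044532	588	10	9	-	9.06	66613.36
HaMPK23-2	HanXRQChr13g0411961	Ha13	-	142634442	142625511	459	18	17	-	9.63	50984.95
HaMPK9-2	HanXRQChr14g0432771	Ha14	-	49683290	49679650	484	10	9	-	6.57	55530.13
HaMPK17	HanXRQChr15g0484561	Ha15	-	84424855	84420653	429	11	10	-	6.24	49909.6
HaMPK18	HanXRQChr15g0495321	Ha15	-	160155012	160149273	563	9	8	-	9.47	64374.62
HaMKK9	HanXRQChr03g0087071	Ha3	-	148424902	148425825	308	1	0	M	6.75	34332.34
HaMKK4	HanXRQChr04g0094171	Ha4	+	471743	472816	351	1	0	C	9.04	38917.18
HaMKK6-1	HanXRQChr09g0238861	Ha9	+	9311933	9322916	357	8	7	-	6.76	39934.36
HaMKK5	HanXRQChr10g0311571	Ha10	+	219604899	219606004	355	1	0	C	9.25	39840.46
HaMKK6-2	HanXRQChr10g0318871	Ha10	+	244056044	244064185	355	8	7	-	7.13	39751.09
HaMKK2	HanXRQChr10g0319531	Ha10	-	245318274	245324118	371	9	8	-	5.43	40967.01
HaMKK1	HanXRQChr12g0354521	Ha12	-	1236278	1243005	358	10	9	-	5.77	39199.81
HaMKK3	HanXRQChr14g0450561	Ha14	-	141579116	141587170	520	12	11	M	5.79	68568.6
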