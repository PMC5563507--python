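chr1	12241	19659	G00001	0	-
chr1	30922	38059	G00002	0	+
chr1	50492	58175	G00003	0	+
chr1	71943	79920	G00004	0	-
chr1	93307	95359	G00005	0	+
chr1	106513	111568	G00006	0	+
chr1	124719	127464	G00007	0	-
chr1	138654	142807	G00008	0	+
chr1	154236	161739	G00009	0	+
chr1	174133	180349	G00010	0	-
chr1	193913	196041	G00011	0	+
chr1	206976	213646	G00012	0	-
chr1	227485	228971	G00013	0	-
chr1	241656	243600	G00014	0	-
chr1	254511	260580	G00015	0	-
chr1	274434	277622	G00016	0	-
chr1	288225	289757	G00017	0	-
chr1	301866	308205	G00018	0	-
chr1	321869	322994	G00019	0	-
chr1	335760	341529	G00020	0	+
chr1	355513	358005	G00021	0	-
chr1	371299	376646	G00022	0	+
chr1	389021	395120	G00023	0	-
chr1	407641	410866	G00024	0	+
chr1	423494	425039	G00025	0	-
chr1	436645	441265	G00026	0	+
chr1	453014	456447	G00027	0	-
chr1	468011	475121	G00028	0	-
chr1	488544	496204	G00029	0	-
chr1	507135	514314	G00030	0	-
chr1	525922	533806	G00031	0	-
chr1	545349	550868	G00032	0	+
chr1	562122	568086	G00033	0	-
chr1	582013	587405	G00034	0	+
chr1	598632	599922	G00035	0	+
chr1	612500	613972	G00036	0	+
chr1	624952	626229	G00037	0	+
chr1	638044	643318	G00038	0	-
chr1	655844	660228	G00039	0	-
chr1	673277	678757	G00040	0	-
chr1	689758	691320	G00041	0	+
chr1	703984	710119	G00042	0	-
chr1	720666	723031	G00043	0	+
chr1	733533	737274	G00044	0	+
chr1	749635	754204	G00045	0	-
chr1	767755	772072	G00046	0	+
chr1	784586	786134	G00047	0	-
chr1	799654	803263	G00048	0	+
chr1	814695	819673	G00049	0	-
chr1	830959	834897	G00050	0	+
chr1	847803	851746	G00051	0	-
chr1	863686	866280	G00052	0	-
chr1	877170	884105	G00053	0	-
chr1	896732	898111	G00054	0	-
chr1	911409	919276	G00055	0	-
chr1	932928	934201	G00056	0	-
chr1	947841	953452	G00057	0	-
chr1	964116	966307	G00058	0	-
chr1	979063	983908	G00059	0	+
chr1	994464	998637	G00060	0	-
chr1	1011142	1014044	G00061	0	-
chr1	1026236	1032220	G00062	0	-
chr1	1045040	1052597	G00063	0	+
chr1	1065493	1071936	G00064	0	-
chr1	1084406	1091142	G00065	0	-
chr1	1101869	1108045	G00066	0	-
chr1	1120994	1126246	G00067	0	-
chr1	1138727	1145131	G00068	0	-
chr1	1158783	1164512	G00069	0	+
chr1	1175330	1182945	G00070	0	-
chr1	1196221	1201722	G00071	0	+
chr1	1212963	1219425	G00072	0	-
chr1	1230026	1234902	G00073	0	-
chr1	1246099	1247571	G00074	0	-
chr1	1258599	1263041	G00075	0	-
chr1	1274988	1280691	G00076	0	+
chr1	1292615	1299599	G00077	0	-
chr1	1313565	1319097	G00078	0	-
chr1	1332777	1335714	G00079	0	-
chr1	1349193	1357012	G00080	0	+
chr1	1368873	1370014	G00081	0	-
chr1	1380641	1384318	G00082	0	+
chr1	1395993	1398688	G00083	0	-
chr1	1410953	1412018	G00084	0	+
chr1	1423599	1427414	G00085	0	+
chr1	1440076	1444326	G00086	0	-
chr1	1456460	1458439	G00087	0	+
chr1	1471918	1477374	G00088	0	+
chr1	1489755	1495481	G00089	0	-
chr1	1506587	1513179	G00090	0	-
chr1	1525002	1528217	G00091	0	+
chr1	1539615	1544302	G00092	0	+
chr1	1555475	1558066	G00093	0	-
chr1	1569649	1572531	G00094	0	-
chr1	1583847	1588825	G00095	0	+
chr1	1601976	1605627	G00096	0	+
chr1	1619272	1621290	G00097	0	-
chr1	1631792	1633720	G00098	0	+
chr1	1646141	1651539	G00099	0	+
chr1	1664744	1671117	G00100	0	+
chr2	13146	15204	G00101	0	-
chr2	29072	36007	G00102	0	+
chr2	47910	54938	G00103	0	+
chr2	66197	69037	G00104	0	+
chr2	79757	82356	G00105	0	+
chr2	94439	102135	G00106	0	-
chr2	115759	119202	G00107	0	+
chr2	130482	132624	G00108	0	-
chr2	146409	147932	G00109	0	-
chr2	160075	166444	G00110	0	+
chr2	177950	180533	G00111	0	-
chr2	192903	196512	G00112	0	-
chr2	210330	214684	G00113	0	-
chr2	227812	231470	G00114	0	-
chr2	243178	244490	G00115	0	+
chr2	257105	263131	G00116	0	-
chr2	275537	277369	G00117	0	-
chr2	288434	294878	G00118	0	+
chr2	307223	309472	G00119	0	+
chr2	322000	325952	G00120	0	-
chr2	339442	344950	G00121	0	-
chr2	357776	363122	G00122	0	-
chr2	374164	381189	G00123	0	-
chr2	392437	393843	G00124	0	+
chr2	405449	407446	G00125	0	-
chr2	420404	422095	G00126	0	+
chr2	435693	440380	G00127	0	+
chr2	451117	457852	G00128	0	+
chr2	471460	475518	G00129	0	-
chr2	487366	491294	G00130	0	-
chr2	502135	508970	G00131	0	-
chr2	521314	528519	G00132	0	+
chr2	539918	545603	G00133	0	+
chr2	559440	561435	G00134	0	+
chr2	573308	579453	G00135	0	+
chr2	593013	597735	G00136	0	-
chr2	608873	610380	G00137	0	-
chr2	622468	623981	G00138	0	+
chr2	636148	644146	G00139	0	+
chr2	657093	659813	G00140	0	+
chr2	671004	674694	G00141	0	+
chr2	686492	691851	G00142	0	-
chr2	705290	706807	G00143	0	+
chr2	720784	723393	G00144	0	-
chr2	735913	739987	G00145	0	+
chr2	751846	754681	G00146	0	+
chr2	768398	771762	G00147	0	+
chr2	782543	784692	G00148	0	-
chr2	796894	798652	G00149	0	+
chr2	812542	818284	G00150	0	+
chr2	830837	835866	G00151	0	-
chr2	848329	849456	G00152	0	+
chr2	862757	866251	G00153	0	+
chr2	878531	885743	G00154	0	+
chr2	897805	905587	G00155	0	-
chr2	919184	923967	G00156	0	-
chr2	937323	943981	G00157	0	-
chr2	957113	965065	G00158	0	+
chr2	977223	984185	G00159	0	+
chr2	995128	997125	G00160	0	+
chr2	1008936	1014626	G00161	0	-
chr2	1026955	1030890	G00162	0	-
chr2	1042034	1047112	G00163	0	-
chr2	1059285	1063934	G00164	0	-
chr2	1074748	1076483	G00165	0	+
chr2	1087903	1090038	G00166	0	-
chr2	1102330	1107752	G00167	0	+
chr2	1118592	1120535	G00168	0	+
chr2	1133342	1136566	G00169	0	+
chr2	1147355	1154379	G00170	0	+
chr2	1166182	1167387	G00171	0	+
chr2	1178909	1185166	G00172	0	+
chr2	1197292	1204299	G00173	0	+
chr2	1218223	1224210	G00174	0	+
chr2	1235966	1241694	G00175	0	-
chr2	1253403	1256998	G00176	0	-
chr2	1270574	1272892	G00177	0	+
chr2	1285284	1293130	G00178	0	-
chr2	1304949	1310285	G00179	0	-
chr2	1323319	1325254	G00180	0	-
chr2	1337469	1344043	G00181	0	-
chr2	1355427	1363198	G00182	0	+
chr2	1374463	1379351	G00183	0	+
chr2	1392761	1398886	G00184	0	-
chr2	1409814	1411556	G00185	0	-
chr2	1423380	1426541	G00186	0	+
chr2	1438682	1442694	G00187	0	-
chr2	1453780	1459252	G00188	0	-
chr2	1470077	1471641	G00189	0	+
chr2	1484829	1488844	G00190	0	-
chr2	1501894	1504502	G00191	0	+
chr2	1515758	1517038	G00192	0	+
chr2	1528013	1529062	G00193	0	-
chr2	1542805	1546307	G00194	0	+
chr2	1558681	1566556	G00195	0	+
chr2	1577708	1585051	G00196	0	-
chr2	1597294	1602152	G00197	0	-
chr2	1613373	1620878	G00198	0	+
chr2	1633225	1636954	G00199	0	+
chr2	1647787	1655042	G00200	0	+
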