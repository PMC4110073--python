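gene_id	transcript_id	chrom	strand	cds_starts	cds_ends
G000	G000.T0	1	-	1001	1039
G001	G001.T0	2	-	1001,1426	1072,1545
G002	G002.T0	3	-	1001,1140,1704,1888	1075,1223,1805,2028
G003	G003.T0	4	-	1001,1308,1699,2136	1138,1400,1788,2201
G004	G004.T0	5	-	1001	1147
G004	G004.T1	5	-	1001	1147
G004	G004.T2	5	-	1001	1147
G005	G005.T0	6	-	1001	1081
G005	G005.T1	6	-	1001	1081
G005	G005.T2	6	-	1001	1081
G006	G006.T0	7	-	1001,1424,1915,2147,2574	1147,1474,1968,2251,2675
G006	G006.T1	7	-	1001,1424,1915,2574	1147,1474,1968,2675
G007	G007.T0	8	-	1001,1437,1710,2007,2453	1066,1574,1847,2036,2503
G007	G007.T1	8	-	1001,1710	1066,1847
G007	G007.T2	8	-	1001,1437,1710,2007,2453	1066,1574,1847,2036,2503
G008	G008.T0	9	+	1001,1554,1929,2123,2659,3269	1078,1583,2012,2203,2808,3307
G009	G009.T0	10	-	1001,1161,1645,2000,2556,2940	1102,1277,1752,2101,2612,3014
G010	G010.T0	11	-	1001,1264,1400,1776	1039,1338,1447,1826
G010	G010.T1	11	-	1001,1264,1400,1776	1039,1338,1447,1826
G011	G011.T0	12	+	1001,1440	1033,1523
G011	G011.T1	12	+	1001,1440	1033,1523
G012	G012.T0	13	+	1001,1394	1138,1504
G012	G012.T1	13	+	1001,1394	1138,1504
G013	G013.T0	14	+	1001	1075
G013	G013.T1	14	+	1001	1075
G014	G014.T0	15	+	1001,1280,1582,1723,2166,2657	1033,1417,1668,1755,2195,2731
G014	G014.T1	15	+	1001,1280,1582,1723,2657	1033,1417,1668,1755,2731
G014	G014.T2	15	+	1001,1280,1582,1723,2166,2657	1033,1417,1668,1755,2195,2731
G015	G015.T0	16	+	1001,1551,1797,2114,2569,3002	1144,1682,1913,2146,2646,3106
G016	G016.T0	17	+	1001	1063
G017	G017.T0	18	+	1001,1477	1072,1563
G018	G018.T0	19	+	1001,1241,1355,1441	1045,1303,1384,1539
G018	G018.T1	19	+	1001,1241,1355	1045,1303,1384
G018	G018.T2	19	+	1001,1241,1355,1441	1045,1303,1384,1539
G019	G019.T0	20	+	1001,1320,1887,2403,2816	1054,1412,2018,2459,2857
G019	G019.T1	20	+	1001,1887,2403,2816	1054,2018,2459,2857
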