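transcript_id	domain_id	start_aa	end_aa
G001.T0	DG001.T0.0	6	44
G001.T0	DG001.T0.1	11	44
G002.T0	DG002.T0.0	38	76
G004.T1	DG004.T1.0	35	48
G004.T2	DG004.T2.0	33	47
G005.T1	DG005.T1.0	14	26
G005.T2	DG005.T2.0	2	26
G006.T0	DG006.T0.0	111	116
G006.T0	DG006.T0.1	74	88
G006.T1	DG006.T1.0	12	40
G007.T0	DG007.T0.0	15	40
G007.T1	DG007.T1.0	12	37
G007.T1	DG007.T1.1	31	42
G007.T2	DG007.T2.0	40	56
G007.T2	DG007.T2.1	12	27
G008.T0	DG008.T0.0	4	38
G009.T0	DG009.T0.0	159	177
G009.T0	DG009.T0.1	158	186
G010.T0	DG010.T0.0	29	68
G010.T0	DG010.T0.1	31	38
G010.T1	DG010.T1.0	57	70
G011.T1	DG011.T1.0	22	31
G012.T0	DG012.T0.0	6	45
G012.T0	DG012.T0.1	43	78
G012.T1	DG012.T1.0	61	65
G013.T0	DG013.T0.0	10	24
G013.T0	DG013.T0.1	8	24
G013.T1	DG013.T1.0	12	24
G013.T1	DG013.T1.1	8	24
G014.T0	DG014.T0.0	52	82
G014.T0	DG014.T0.1	54	82
G014.T1	DG014.T1.0	66	100
G014.T2	DG014.T2.0	110	117
G014.T2	DG014.T2.1	63	88
G015.T0	DG015.T0.0	162	173
G016.T0	DG016.T0.0	6	16
G017.T0	DG017.T0.0	15	25
G017.T0	DG017.T0.1	7	24
G018.T0	DG018.T0.0	15	32
G018.T1	DG018.T1.0	16	45
G018.T1	DG018.T1.1	31	45
G018.T2	DG018.T2.0	24	59
G018.T2	DG018.T2.1	48	72
G019.T0	DG019.T0.0	16	45
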