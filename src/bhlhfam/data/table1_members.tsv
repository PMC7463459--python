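# D. officinale bHLH family membership table (gene, locus, protein accession, clade)
gene	locus	accession	clade
DobHLH1	LOC110116721	XP_020706080.1	1
DobHLH2	LOC110115756	XP_020704772.1	1
DobHLH3	LOC110107102	XP_020692919.1	1
DobHLH4	LOC110096422	XP_020678032.1	1
DobHLH5	LOC110116474	XP_020705700.1	1
DobHLH6	LOC110098508	XP_020681021.1	1
DobHLH7	LOC110111619	XP_020699225.1	1
DobHLH8	LOC110112576	XP_020700508.1	1
DobHLH9	LOC110108487	XP_020694816.2	1
DobHLH10	LOC110110298	XP_020697356.1	2
DobHLH11	LOC110093619	XP_020674221.1	2
DobHLH12	LOC110115484	XP_020704390.1	2
DobHLH13	LOC110093741	XP_020674407.1	3
DobHLH14	LOC110102219	XP_020686105.1	3
DobHLH15	LOC110098909	XP_020681520.1	3
DobHLH16	LOC110107046	XP_028551992.1	3
DobHLH17	LOC110096269	XP_020677790.1	3
DobHLH18	LOC110116147	XP_020705280.1	4
DobHLH19	LOC110094813	XP_028551573.1	4
DobHLH20	LOC110107826	XP_020693884.2	4
DobHLH21	LOC110094726	XP_020675682.1	4
DobHLH22	LOC110114654	XP_020703261.1	5
DobHLH23	LOC110111891	XP_020699606.1	5
DobHLH24	LOC110097687	XP_020679864.1	5
DobHLH25	LOC110103241	XP_020687528.1	6
DobHLH26	LOC110094094	XP_020674906.1	6
DobHLH27	LOC110116682	XP_020706025.1	6
DobHLH28	LOC110099101	XP_020681804.1	6
DobHLH29	LOC110113808	XP_020702166.2	6
DobHLH30	LOC110094435	XP_020675326.1	6
DobHLH31	LOC110116479	XP_020705705.1	6
DobHLH32	LOC110114462	XP_020703009.1	6
DobHLH33	LOC110092865	XP_020673218.1	6
DobHLH34	LOC110109085	XP_020695652.1	7
DobHLH35	LOC110096203	XP_020677673.1	7
DobHLH36	LOC110112097	XP_020699850.1	7
DobHLH37	LOC110107930	XP_020694038.1	8
DobHLH38	LOC110115493	XP_020704404.1	8
DobHLH39	LOC110094861	XP_020675853.1	8
DobHLH40	LOC110112072	XP_020699818.1	8
DobHLH41	LOC110114469	XP_028556744.1	9
DobHLH42	LOC110107963	XP_020694091.1	9
DobHLH43	LOC110106259	XP_028550041.1	9
DobHLH44	LOC110107318	XP_028547365.1	10
DobHLH45	LOC110103817	XP_028551326.1	10
DobHLH46	LOC110114754	XP_020703396.1	10
DobHLH47	LOC110107832	XP_020693899.1	10
DobHLH48	LOC110107031	XP_020692824.1	10
DobHLH49	LOC110098511	XP_020681024.1	10
DobHLH50	LOC110116300	XP_020705489.1	10
DobHLH51	LOC114579352	XP_028549432.1	10
DobHLH52	LOC110095032	XP_020676060.1	11
DobHLH53	LOC110113329	XP_020701532.1	11
DobHLH54	LOC110113204	XP_020701328.1	11
DobHLH55	LOC110114625	XP_020703217.1	12
DobHLH56	LOC110106166	XP_020691604.1	12
DobHLH57	LOC110112285	XP_020700113.1	12
DobHLH58	LOC110108563	XP_020694908.1	12
DobHLH59	LOC110101829	XP_020685553.1	13
DobHLH60	LOC110095526	XP_020676768.1	13
DobHLH61	LOC110111433	XP_028555769.1	13
DobHLH62	LOC110093428	XP_020673967.1	13
DobHLH63	LOC110104725	XP_020689612.1	14
DobHLH64	LOC110102342	XP_028552167.1	14
DobHLH65	LOC110107722	XP_020693735.1	14
DobHLH66	LOC110100649	XP_020683910.1	14
DobHLH67	LOC110114258	XP_028550306.1	14
DobHLH68	LOC110114447	XP_028556766.1	14
DobHLH69	LOC110109277	XP_028547820.1	14
DobHLH70	LOC110096494	XP_020678137.1	14
DobHLH71	LOC110111863	XP_028551171.1	14
DobHLH72	LOC110107433	XP_028552737.1	14
DobHLH73	LOC110114740	XP_020703378.2	14
DobHLH74	LOC110095482	XP_020676694.1	14
DobHLH75	LOC110099461	XP_020682274.1	14
DobHLH76	LOC110099214	XP_028548138.1	14
DobHLH77	LOC110098199	XP_020680601.1	15
DobHLH78	LOC110098270	XP_020680696.1	15
DobHLH79	LOC110094287	XP_020675140.1	15
DobHLH80	LOC110113891	XP_020702260.1	15
DobHLH81	LOC110112441	XP_020700324.1	15
DobHLH82	LOC110101026	XP_020684454.1	15
DobHLH83	LOC110111081	XP_020698439.1	15
DobHLH84	LOC110104845	XP_020689772.1	15
DobHLH85	LOC110095998	XP_020677402.1	15
DobHLH86	LOC110110399	XP_020697513.2	15
DobHLH87	LOC110109507	XP_028547425.1	15
DobHLH88	LOC114578594	XP_028547764.1	15
DobHLH89	LOC110105526	XP_020690722.2	15
DobHLH90	LOC110100961	XP_020684346.1	15
DobHLH91	LOC110112336	XP_020700191.1	16
DobHLH92	LOC110110400	XP_020697514.1	17
DobHLH93	LOC110112399	XP_028555091.1	17
DobHLH94	LOC110108630	XP_020695011.1	17
DobHLH95	LOC110110529	XP_020697710.1	17
DobHLH96	LOC110108826	XP_020695307.1	17
DobHLH97	LOC110105593	XP_020690812.1	17
DobHLH98	LOC110100228	XP_020683310.1	18
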