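##gff-version 3
molecule_1	potato_mt	CDS	3860	4118	.	+	.	gene_id=nad1e_1
molecule_1	potato_mt	CDS	12570	12929	.	-	.	gene_id=orf119
molecule_1	potato_mt	CDS	13197	14732	.	-	.	gene_id=atp1
molecule_1	potato_mt	CDS	31292	32122	.	-	.	gene_id=mttB
molecule_1	potato_mt	CDS	32244	33041	.	-	.	gene_id=orf265a
molecule_1	potato_mt	rRNA	33385	36879	.	-	.	gene_id=rrn26S
molecule_1	potato_mt	CDS	50394	50581	.	-	.	gene_id=nad2cde
molecule_1	potato_mt	CDS	52050	52622	.	-	.	gene_id=nad2cde
molecule_1	potato_mt	CDS	55094	55254	.	-	.	gene_id=nad2cde
molecule_1	potato_mt	CDS	61695	62910	.	-	.	gene_id=nad5ab
molecule_1	potato_mt	CDS	63755	63984	.	-	.	gene_id=nad5ab
molecule_1	potato_mt	CDS	64989	65077	.	-	.	gene_id=nad4
molecule_1	potato_mt	CDS	67705	68127	.	-	.	gene_id=nad4
molecule_1	potato_mt	CDS	71259	71773	.	-	.	gene_id=nad4
molecule_1	potato_mt	CDS	73185	73645	.	-	.	gene_id=nad4
molecule_1	potato_mt	CDS	73849	74226	.	-	.	gene_id=orf125
molecule_1	potato_mt	CDS	78169	78912	.	-	.	gene_id=orf247
molecule_1	potato_mt	CDS	90192	91013	.	+	.	gene_id=rps4
molecule_1	potato_mt	CDS	91707	92360	.	+	.	gene_id=nad6
molecule_1	potato_mt	CDS	98027	98329	.	+	.	gene_id=nad4L
molecule_1	potato_mt	CDS	98518	99114	.	+	.	gene_id=atp4
molecule_1	potato_mt	CDS	109344	110660	.	-	.	gene_id=orf438_1
molecule_1	potato_mt	CDS	110784	111209	.	-	.	gene_id=orf141_1
molecule_1	potato_mt	rRNA	111720	111838	.	-	.	gene_id=rrn5S_1
molecule_1	potato_mt	rRNA	112001	113946	.	-	.	gene_id=rrn18S_1
molecule_1	potato_mt	CDS	117275	118189	.	+	.	gene_id=orf304_1
molecule_1	potato_mt	CDS	118391	118449	.	+	.	gene_id=nad1d_1
molecule_1	potato_mt	CDS	119111	121087	.	+	.	gene_id=matR
molecule_1	potato_mt	CDS	125647	125793	.	-	.	gene_id=nad5de
molecule_1	potato_mt	CDS	126889	127283	.	-	.	gene_id=nad5de
molecule_1	potato_mt	CDS	127397	127855	.	-	.	gene_id=orf152
molecule_1	potato_mt	CDS	128459	128776	.	-	.	gene_id=orf105
molecule_1	potato_mt	CDS	128839	129318	.	-	.	gene_id=orf159
molecule_1	potato_mt	CDS	139197	139610	.	-	.	gene_id=orf137
molecule_1	potato_mt	CDS	148955	149339	.	+	.	gene_id=nad1a
molecule_1	potato_mt	CDS	159585	159869	.	+	.	gene_id=rps19_1
molecule_1	potato_mt	CDS	159883	159956	.	+	.	gene_id=rps3_1
molecule_1	potato_mt	CDS	161026	162643	.	+	.	gene_id=rps3_1
molecule_1	potato_mt	CDS	162534	163049	.	+	.	gene_id=rpl16_1
molecule_1	potato_mt	CDS	163299	163680	.	+	.	gene_id=cox2_1
molecule_1	potato_mt	CDS	165066	165466	.	+	.	gene_id=cox2_1
molecule_1	potato_mt	CDS	172753	173583	.	+	.	gene_id=ccmC
molecule_1	potato_mt	CDS	208754	209038	.	+	.	gene_id=rps19_2
molecule_1	potato_mt	CDS	209052	209125	.	+	.	gene_id=rps3_2
molecule_1	potato_mt	CDS	210195	211812	.	+	.	gene_id=rps3_2
molecule_1	potato_mt	CDS	211703	212218	.	+	.	gene_id=rpl16_2
molecule_1	potato_mt	CDS	212468	212849	.	+	.	gene_id=cox2_2
molecule_1	potato_mt	CDS	214235	214635	.	+	.	gene_id=cox2_2
molecule_1	potato_mt	CDS	233142	233375	.	+	.	gene_id=orf77
molecule_1	potato_mt	CDS	233431	233689	.	+	.	gene_id=nad1e_2
molecule_1	potato_mt	CDS	233940	235106	.	+	.	gene_id=atp6
molecule_1	potato_mt	CDS	243146	243379	.	+	.	gene_id=atp9
molecule_1	potato_mt	CDS	246225	246246	.	+	.	gene_id=nad5c
molecule_1	potato_mt	CDS	246314	246799	.	+	.	gene_id=orf161
molecule_1	potato_mt	CDS	271765	272026	.	-	.	gene_id=nad7
molecule_1	potato_mt	CDS	273770	274477	.	-	.	gene_id=nad7
molecule_1	potato_mt	CDS	275936	276004	.	-	.	gene_id=nad7
molecule_1	potato_mt	CDS	276920	277062	.	-	.	gene_id=nad7
molecule_1	potato_mt	CDS	278419	278730	.	-	.	gene_id=orf103
molecule_1	potato_mt	CDS	292250	292441	.	-	.	gene_id=nad1bc
molecule_1	potato_mt	CDS	293925	294007	.	-	.	gene_id=nad1bc
molecule_1	potato_mt	CDS	294547	294897	.	-	.	gene_id=rps13
molecule_1	potato_mt	CDS	295623	295681	.	-	.	gene_id=nad1d_2
molecule_1	potato_mt	CDS	295883	296797	.	-	.	gene_id=orf304_2
molecule_1	potato_mt	rRNA	300126	302071	.	+	.	gene_id=rrn18S_2
molecule_1	potato_mt	rRNA	302234	302352	.	+	.	gene_id=rrn5S_2
molecule_1	potato_mt	CDS	302863	303288	.	+	.	gene_id=orf141_2
molecule_1	potato_mt	CDS	303412	304728	.	+	.	gene_id=orf438_2
molecule_1	potato_mt	CDS	310786	311748	.	-	.	gene_id=orf320
molecule_2	potato_mt	CDS	6136	6685	.	-	.	gene_id=ccmFC
molecule_2	potato_mt	CDS	7635	8401	.	-	.	gene_id=ccmFC
molecule_2	potato_mt	CDS	33524	34705	.	-	.	gene_id=cob
molecule_2	potato_mt	CDS	51176	51589	.	-	.	gene_id=sdh4
molecule_2	potato_mt	CDS	51517	52314	.	-	.	gene_id=cox3
molecule_2	potato_mt	CDS	52947	53417	.	-	.	gene_id=atp8
molecule_2	potato_mt	CDS	54391	54747	.	-	.	gene_id=orf118
molecule_2	potato_mt	CDS	54964	55635	.	-	.	gene_id=rps1
molecule_2	potato_mt	CDS	71926	73737	.	-	.	gene_id=ccmFN
molecule_2	potato_mt	CDS	76329	77825	.	-	.	gene_id=cox1
molecule_2	potato_mt	CDS	78075	78187	.	-	.	gene_id=rps10
molecule_2	potato_mt	CDS	78963	79212	.	-	.	gene_id=rps10
molecule_2	potato_mt	pseudogene	81682	82051	.	-	.	gene_id=rps14
molecule_2	potato_mt	CDS	82053	82613	.	-	.	gene_id=rpl5
molecule_2	potato_mt	CDS	99496	99867	.	-	.	gene_id=rps12
molecule_2	potato_mt	CDS	99916	100272	.	-	.	gene_id=nad3
molecule_2	potato_mt	CDS	100423	101220	.	-	.	gene_id=orf265b
molecule_3	potato_mt	CDS	9945	10565	.	+	.	gene_id=ccmB
molecule_3	potato_mt	CDS	16440	16919	.	-	.	gene_id=rpl10
molecule_3	potato_mt	CDS	17204	17320	.	-	.	gene_id=rpl2
molecule_3	potato_mt	CDS	19230	20114	.	-	.	gene_id=rpl2
molecule_3	potato_mt	CDS	20294	20926	.	-	.	gene_id=orf210
molecule_3	potato_mt	CDS	35400	35726	.	+	.	gene_id=sdh3
molecule_3	potato_mt	CDS	36302	36453	.	+	.	gene_id=nad2ab
molecule_3	potato_mt	CDS	37470	37862	.	+	.	gene_id=nad2ab
molecule_3	potato_mt	CDS	41589	42161	.	-	.	gene_id=nad9
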