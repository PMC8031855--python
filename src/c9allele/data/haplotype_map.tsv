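rs_id	chrom	pos	kind	R	F	K	P	N	J	Q	Z	specific_for
rs41272893	chr9	27573800	snp	A	A	A	A	G	A	A	A	N
rs78074330	chr9	27573541	snp	A	A	A	A	G	A	A	A	N
rs117462033	chr9	27573282	snp	C	C	C	T	C	C	T	C	
rs112048460	chr9	27573023	snp	C	C	C	C	T	C	C	C	N
rs2282240	chr9	27572764	snp	C	T	C	C	C	C	C	C	F
rs2282241	chr9	27572505	snp	C	A	C	A	C	C	A	A	
rs4520261	chr9	27572246	snp	C	C	C	C	T	C	C	C	N
rs17696653	chr9	27571987	snp	T	T	T	T	C	T	T	T	N
rs3849946	chr9	27571728	snp	C	A	C	A	C	C	A	A	
rs145319692	chr9	27571469	short_repeat	6	5	5	5	5	5	5	5	R
rs78900326	chr9	27571210	snp	C	C	C	C	T	C	C	C	N
rs700824	chr9	27570951	snp	T	T	C	T	T	C	T	T	
rs700825	chr9	27570692	snp	G	G	G	G	G	A	G	G	J
rs4879572	chr9	27570433	snp	A	A/G	A	A	A	A	A	A	
rs76602706	chr9	27570174	snp	T	T	T	T	C	T	T	T	N
rs13284967	chr9	27569915	snp	C	T	C	T	C	C	T	T	
rs111630075	chr9	27569656	snp	G	G	G	G	A	G	G	G	N
rs10812619	chr9	27569397	snp	T	C	T	C	T	T	C	C	
rs72710405	chr9	27569138	snp	G	G	G	A	G	G	G	G	P
rs111653040	chr9	27568879	snp	A	A/G	A	A	A	A	A	A	
rs3849945	chr9	27568620	snp	G	A	A	A	A	A	A	A	R
rs72710403	chr9	27568361	snp	A	A	A	G	A	A	A	A	P
rs77534147	chr9	27568102	indel	AC	AC	AC	AC	AC	--	AC	AC	J
rs7875392	chr9	27567843	snp	C	C	G	C	C	C	C	C	K
rs17769300	chr9	27567584	snp	G	G	G	G	C	G	G	G	N
rs7872223	chr9	27567325	snp	C	C	A	C	C	C	C	C	K
rs10967988	chr9	27567066	snp	G	T	G	T	G	G	T	T	
rs10757669	chr9	27566807	snp	G	G	A	G	G	G	G	G	K
rs41272891	chr9	27566548	snp	G	G	G	G	A	G	G	G	N
rs10757668	chr9	27566289	snp	C	C	T	C	C	C	C	C	K
rs2120721	chr9	27566030	snp	G	C	G	C	C	C	C	C	
rs1031153	chr9	27565771	snp	C	T	C	C	C	C	C	C	F
rs10757667	chr9	27565512	snp	A	A	C	A	A	A	A	A	K
rs10967986	chr9	27565253	snp	G	A	G	A	G	A	A	A	
rs10757666	chr9	27564994	snp	A	A	T	A	T	A	A	A	
rs10812618	chr9	27564735	snp	T	T	G	T	T	T	T	T	K
rs142843265	chr9	27564476	indel	--	AG	AG	AG	AG	AG	AG	AG	R
rs2492816	chr9	27564217	snp	A	G	G	A	A	A	G	A	
rs7859060	chr9	27563958	snp	A	A	G	A	A	A	A	A	K
rs7874565	chr9	27563699	snp	T	T	C	T	T	T	T	T	K
rs10812617	chr9	27563440	snp	T	T	C	T	T	T	T	T	K
rs7858531	chr9	27563181	snp	A	A	G	A	A	A	A	A	K
rs2453555	chr9	27562922	snp	A	G	G	G	G	G	G	G	R
rs2484319	chr9	27562663	snp	C	A	A	A	A	A	A	A	R
rs10441712	chr9	27562404	snp	T	T	C	C	C	C	T	C	
rs10812616	chr9	27562145	snp	T	T	A	A	A	A	T	A	
rs10812615	chr9	27561886	snp	T	T	C	C	C	C	T	C	
rs34366576	chr9	27561627	snp	A	A	A	G	G	G	A	G	
rs2453554	chr9	27561368	snp	T	C	C	C	C	C	C	C	R
rs17769294	chr9	27561109	snp	T	T	T	C	T	T	T	T	P
rs774359	chr9	27560850	snp	C	T	T	T	C	T	T	T	
rs12347222	chr9	27560591	snp	G	G	G	T	G	T	T	T	
rs3849944	chr9	27560332	snp	T	T	C	C	C	C	C	C	
rs10967985	chr9	27560073	snp	G	G	A	G	G	G	G	G	K
rs774358	chr9	27559814	snp	A	T	A	A	A	A	A	A	F
rs28526385	chr9	27559555	snp	T	T	T	C	C	C	C	C	
rs774357	chr9	27559296	snp	A	G	G	G	G	G	G	G	R
rs1565948	chr9	27559037	snp	G	G	A	A	A	A	A	A	
rs774356	chr9	27558778	snp	C	T	T	T	C	T	T	T	
rs7860526	chr9	27558519	snp	A	A	G	A	A	A	A	A	K
rs2297694	chr9	27558260	snp	C	C	C	G	G	G	G	G	
rs10812614	chr9	27558001	snp	A	T	A	A	A	A	A	A	F
rs4879566	chr9	27557742	snp	T	T	T	C	C	C	C	C	
rs4879565	chr9	27557483	snp	T	T	T	A	T	A	A	A	
rs67245195	chr9	27557224	snp	A	A	A	A	A	T	A	A	J
rs10757665	chr9	27556965	snp	T	T	C	T	T	T	T	T	K
rs4879564	chr9	27556706	snp	C	C	C	T	C	T	C	T	
rs62538126	chr9	27556447	snp	C	C	C/A	C	C	C	C	C	
rs112616482	chr9	27556188	snp	A	A	A	A	C	A	A	A	N
rs700828	chr9	27555929	snp	C	T	T	T	C	T	T	T	
rs10812613	chr9	27555670	snp	T	T	C	T	T	T	T	T	K
rs17835861	chr9	27555411	snp	C	C	C	G	G	G	C	G	
rs34670748	chr9	27555152	snp	G	G/A	G	G	G	G	G	G	
rs111253152	chr9	27554893	snp	T	T	T	T	A	T	T	T	N
rs1022902	chr9	27554634	snp	G	G	G	A	G	A	G	A	
rs17769246	chr9	27554375	snp	T	T	T	T	G	T	T	T	N
rs188460764	chr9	27554116	snp	T/A	T	T	T	A	T	T	T	
rs76412392	chr9	27553857	snp	T	T	T	T	T	T	T	A	Z
rs10967984	chr9	27553598	snp	C	T	C	T	C	T	T	T	
rs10967983	chr9	27553339	snp	T	T	A	T	T	T	T	T	K
rs60613335	chr9	27553080	snp	A	A	A	A	G	A	A	A	N
rs35815580	chr9	27552821	snp	G	G	G	G	G	A	G	G	J
rs12686452	chr9	27552562	snp	T	T	T	C	T	C	C	C	
rs10124158	chr9	27552303	snp	T	T	G	G	G	G	G	G	
rs12349820	chr9	27552044	snp	T	T	C	T	T	T	T	T	K
rs80272464	chr9	27551785	snp	G	G	C	G	G	G	G	G	K
rs113076260	chr9	27551526	snp	T	T	T	T	C	T	T	T	N
rs68005046	chr9	27551267	snp	G	G	G	G	G	A	G	G	J
rs4878487	chr9	27551008	snp	T	T	T	C	T	C	T	C	
rs71510499	chr9	27550749	snp	C	C	C	C	C	T	C	C	J
rs10967981	chr9	27550490	snp	T	C	T	T	T	T	C	T	
rs12347201	chr9	27550231	snp	T	T	C	T	T	T	T	T	K
rs117867610	chr9	27549972	snp	C	C	C	C	C	C	C	T	Z
rs2453565	chr9	27549713	snp	T	C	C	C	C	C	C	C	R
rs62538125	chr9	27549454	snp	A	A	C	A	A	A	A	A	K
rs10120735	chr9	27549195	snp	T	T	T	T	C	T	T	T	N
rs773723	chr9	27548936	snp	G	G	T	T	G	T	T	T	
rs10967979	chr9	27548677	snp	A	A	C	A	A	A	A	A	K
rs72727512	chr9	27548418	snp	C	C	C	G	C	C	G	C	
rs2305045	chr9	27548159	snp	A	A	A	A	A	A	A	C	Z
rs73440933	chr9	27547900	snp	A	A	A	A	G	A	A	A	N
rs200583482	chr9	27547641	indel	-	-	-	-	A	-	-	-	N
rs3739526	chr9	27547382	snp	G	G	G	T	G	T	G	T	
rs13691	chr9	27547123	snp	G	A	G	G	G	G	G	G	F
rs9103	chr9	27546864	snp	A	A	G	A	A	A	A	A	K
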