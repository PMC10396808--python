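id	chrom	pos	ea	ra	eaf	f_x	beta_x	p_x	n_x	eaf_outcome	hd_y	p_y	hd_cs	p_cs
rs2794520	1	159678816	C	T	0.365	961.9	0.247	7.23e-200	59605	0.366	-0.230	0.887	0.018	0.989
rs12133641	1	154428283	G	A	0.433	197.0	-0.116	3.52e-47	59605	0.429	-1.860	0.210	-0.454	0.701
rs71086917	1	159455503	insA	-	0.452	61.2	-0.064	6.54e-16	59605	0.414	0.127	0.938	0.934	0.493
rs1260326	2	27730940	C	T	0.450	133.0	-0.090	1.31e-29	59605	0.452	3.017	0.050	1.535	0.201
rs7383869	7	22748190	A	G	0.362	164.1	0.105	3.53e-37	59605	0.365	0.571	0.693	0.562	0.620
rs79320731	12	121422449	CTGACTGGCACTCAGCA	T	0.455	461.1	-0.169	1.22e-99	59605	0.454	-0.929	0.530	-1.999	0.095
rs429358	19	45411941	C	T	0.096	587.6	-0.321	3.53e-125	59605	0.057	8.684	0.011	7.331	0.014
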