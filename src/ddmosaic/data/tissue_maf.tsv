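family_id	member_role	tissue	platform	maf_pct	ci_low_pct	ci_high_pct	chr	pos_hg19_1based	ref	alt	cdna	protein	origin
A015	father	sperm	mDDPCR	0.03	0.03	0.04	19	42474436	C	T	c.2443G>A	p.(Glu815Lys)	paternal
A015	father	blood	mDDPCR	0.01	0.01	0.02	19	42474436	C	T	c.2443G>A	p.(Glu815Lys)	paternal
A015	father	buccal	mDDPCR	NA	NA	NA	19	42474436	C	T	c.2443G>A	p.(Glu815Lys)	paternal
A015	father	saliva	mDDPCR	NA	NA	NA	19	42474436	C	T	c.2443G>A	p.(Glu815Lys)	paternal
A015	father	hair	mDDPCR	NA	NA	NA	19	42474436	C	T	c.2443G>A	p.(Glu815Lys)	paternal
A015	father	urine	mDDPCR	NA	NA	NA	19	42474436	C	T	c.2443G>A	p.(Glu815Lys)	paternal
A015	father	skin	mDDPCR	NA	NA	NA	19	42474436	C	T	c.2443G>A	p.(Glu815Lys)	paternal
A052	father	sperm	mDDPCR	NA	NA	NA	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	mother	blood	mDDPCR	18.82	18.51	19.14	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	mother	buccal	mDDPCR	17.60	17.19	18.02	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	mother	saliva	mDDPCR	20.51	20.27	20.75	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	mother	hair	mDDPCR	28.25	27.58	28.93	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	mother	urine	mDDPCR	23.24	22.48	24.01	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	mother	skin	mDDPCR	14.13	13.64	14.62	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A065	father	sperm	mDDPCR	12.42	12.24	12.60	19	42474557	C	T	c.2401G>A	p.(Asp801Asn)	paternal
A065	father	blood	mDDPCR	0.01	0.01	0.02	19	42474557	C	T	c.2401G>A	p.(Asp801Asn)	paternal
A065	father	buccal	mDDPCR	0.01	0.00	0.04	19	42474557	C	T	c.2401G>A	p.(Asp801Asn)	paternal
A065	father	saliva	mDDPCR	0.01	0.00	0.01	19	42474557	C	T	c.2401G>A	p.(Asp801Asn)	paternal
A065	father	hair	mDDPCR	0.00	0.00	0.98	19	42474557	C	T	c.2401G>A	p.(Asp801Asn)	paternal
A065	father	urine	mDDPCR	0.00	0.00	1.73	19	42474557	C	T	c.2401G>A	p.(Asp801Asn)	paternal
A065	father	skin	mDDPCR	NA	NA	NA	19	42474557	C	T	c.2401G>A	p.(Asp801Asn)	paternal
A066	father	sperm	mDDPCR	6.41	6.26	6.56	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	father	blood	mDDPCR	7.53	7.33	7.74	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	father	buccal	mDDPCR	6.48	6.34	6.62	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	father	saliva	mDDPCR	8.05	7.82	8.29	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	father	hair	mDDPCR	9.64	9.39	9.90	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	father	urine	mDDPCR	5.49	4.17	7.09	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	father	skin	mDDPCR	7.70	7.48	7.93	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A067	father	sperm	mDDPCR	0.00	0.00	0.00	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	mother	blood	mDDPCR	7.65	7.40	7.91	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	mother	buccal	mDDPCR	4.87	4.52	5.23	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	mother	saliva	mDDPCR	8.08	7.90	8.27	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	mother	hair	mDDPCR	0.05	0.00	0.25	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	mother	urine	mDDPCR	5.90	4.80	7.16	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	mother	skin	mDDPCR	NA	NA	NA	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A112	father	sperm	mDDPCR	33.03	32.78	33.27	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	father	blood	mDDPCR	17.05	16.82	17.28	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	father	buccal	mDDPCR	13.88	13.30	14.49	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	father	saliva	mDDPCR	16.92	16.65	17.18	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	father	hair	mDDPCR	21.66	21.37	21.95	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	father	urine	mDDPCR	0.00	0.00	0.00	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	father	skin	mDDPCR	14.03	13.59	14.49	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
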