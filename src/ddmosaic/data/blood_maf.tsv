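family_id	member_role	tissue	platform	maf_pct	ci_low_pct	ci_high_pct	chr	pos_hg19_1based	ref	alt	cdna	protein	origin
A012	father	blood	mDDPCR	0.00	0.00	0.01	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	proband
A012	father	blood	PASM	0.0	0.0	0.6	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	proband
A012	mother	blood	mDDPCR	0.01	0.00	0.03	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	proband
A012	mother	blood	PASM	0.0	0.0	0.2	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	proband
A012	control	blood	mDDPCR	0.00	0.00	0.02	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	proband
A012	control	blood	PASM	0.0	0.0	0.2	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	proband
A012	proband	blood	mDDPCR	44.19	43.72	44.66	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	proband
A012	proband	blood	PASM	32.5	28.5	36.6	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	proband
A052	father	blood	mDDPCR	0.00	0.00	0.01	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	father	blood	PASM	0.0	0.0	0.0	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	mother	blood	mDDPCR	18.82	18.51	19.14	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	mother	blood	PASM	17.1	16.7	17.6	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	control	blood	mDDPCR	0.00	0.00	0.02	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	control	blood	PASM	0.0	0.0	0.0	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	proband	blood	mDDPCR	49.98	49.60	50.35	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A052	proband	blood	PASM	50.9	49.9	51.9	19	42473598	C	T	c.2677G>A	p.(Gly893Arg)	maternal
A066	father	blood	mDDPCR	7.53	7.33	7.74	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	father	blood	PASM	4.5	2.8	6.7	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	mother	blood	mDDPCR	0.01	0.00	0.02	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	mother	blood	PASM	0.0	0.0	0.4	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	control	blood	mDDPCR	0.00	0.00	0.02	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	control	blood	PASM	0.0	0.0	0.2	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	proband	blood	mDDPCR	50.00	49.69	50.30	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A066	proband	blood	PASM	44.3	41.1	47.4	19	42471896	C	G	c.2839G>C	p.(Gly947Arg)	paternal
A067	father	blood	mDDPCR	0.00	0.00	0.01	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	father	blood	PASM	0.2	0.0	1.3	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	mother	blood	mDDPCR	7.65	7.40	7.91	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	mother	blood	PASM	6.4	5.7	7.2	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	control	blood	mDDPCR	0.00	0.00	0.01	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	control	blood	PASM	0.0	0.0	0.2	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	proband	blood	mDDPCR	50.41	49.88	50.95	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A067	proband	blood	PASM	49.2	48.0	50.5	19	42471896	C	T	c.2839G>A	p.(Gly947Arg)	maternal
A112	father	blood	mDDPCR	17.05	16.82	17.28	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	father	blood	PASM	18.8	17.7	19.9	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	mother	blood	mDDPCR	0.00	0.00	0.01	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	mother	blood	PASM	0.0	0.0	0.1	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	control	blood	mDDPCR	0.0	0.00	0.01	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	control	blood	PASM	NA	NA	NA	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	proband	blood	mDDPCR	49.93	49.64	50.22	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
A112	proband	blood	PASM	52.6	50.7	54.6	19	42486187_42486189	GAA		c.1063_1065del	p.(Glu355del)	paternal
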