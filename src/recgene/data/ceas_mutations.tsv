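number	chrom	pos_hg19	exon	cdna	protein3	protein1	effect	cnsu_alt	cnsu_total	control	hgvd	cd
1	3	133674014	4	c.421G>T	Glu141X	E141X	nonsense	1	32		1/858	1/1194
2	3	133673888	4	c.547G>A	Gly183Arg	G183R	missense	0	32		0	1/1194
3	3	133672567	5	c.664G>A	Gly222Arg	G222R	missense	4	32	0	1/858	0
4	3	133667736	7	c.940+1G>A			splice_site	19	32	3/1494	3/1330	11/1206
5	3	133664028	10	c.1372G>T	Val458Phe	V458F	missense	2	32		0	0
6	3	133663938	10	c.1461+1G>C			splice_site	2	32	0	0	0
7	3	133654625	13	c.1807C>T	Arg603X	R603X	nonsense	4	32	0	0	0
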