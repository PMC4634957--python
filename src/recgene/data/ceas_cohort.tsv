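patient	sample_id	sex	consanguinity_degree	family_history	mutation_types	genotype	age_onset	age_diagnosis	symptoms	disease_sites	hemoglobin	serum_protein	crp	surgery	screening_group
1	A_V_2	F	5	No	SS/SS	c.1461+1G>C/c.1461+1G>C	17	43	Anemia	I	9.6	4.6	0.5	+	wes
2	B_IV_3	F	3	No	SS/SS	c.940+1G>A/c.940+1G>A	37	38	Anemia	S,I	9.5	6.7	0.5	+	wes
3	C_IV_3	F	3	No	SS/SS	c.940+1G>A/c.940+1G>A	11	39	Anemia,abdominal pain	I				+	wes
4	D_II_4	F		Yes	NS/NS	Gly222Arg/Arg603X	53	55	Anemia	S,I	9.7	5.2	0.1	-	wes
5	D_II_5	F		Yes	NS/NS	Gly222Arg/Arg603X	12	22	Anemia,abdominal pain	S,D,I	9.7	5.8	0.3	+	wes
6		F		Yes	SS/SS	c.940+1G>A/c.940+1G>A	12	51	Anemia	D,I	4.8	5.3	0.0	+	sanger
7		F		Yes	SS/SS	c.940+1G>A/c.940+1G>A	16	41	Anemia	D,I	10.7	5.8	0.9	+	sanger
8		F	3	No	SS/SS	c.940+1G>A/c.940+1G>A	13	29	Anemia	D,I	8.4	5.0	0.2	+	sanger
9		F	3	No	NS/NS	Val458Phe/Val458Phe	40	66	Anemia,hypoproteinemia	I	9.5	4.4	0.6	+	sanger
10		F		No	NS/NS	Glu141X/Arg603X	50	59	Anemia,abdominal pain	I	8.5	6.3	0.1	-	sanger
11		M		No	SS/SS	c.940+1G>A/c.940+1G>A	20	41	Anemia,hypoproteinemia	D,J,I	11.0	4.8	1.6	-	sanger
12		M		No	NS/NS	Gly222Arg/Gly222Arg	15	63	Anemia,hypoproteinemia	J,I	8.1	5.7	0.4	+	sanger
13		F	3	No	SS/SS	c.940+1G>A/c.940+1G>A	51	51	Anemia,abdominal pain	S,I	11.2	6.6	0.1	+	sanger
14		F	3	Yes	SS/SS	c.940+1G>A/c.940+1G>A	7	7	Anemia,abdominal pain	S,D,J,I	11.1	5.8	0.1	+	sanger
15		F		No	SS/NS	c.940+1G>A/Arg603X	18	23	Anemia,abdominal pain	D,I	7.8	3.8	0.0	+	sanger
16		M	NA	No	SS/SS	c.940+1G>A/c.940+1G>A	12	31	Anemia,edema	D,I	7.4	8.2	0.1	+	sanger
17		M		No	SS/NS	c.940+1G>A/Gly183Arg	1		Anemia,edema	J,I	2.3	5.1	0.4	+	cd
18		F		No	SS/NS	c.940+1G>A/Glu141X	52		Anemia,edema	J,I	9.5	5.2	0.1	-	cd
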