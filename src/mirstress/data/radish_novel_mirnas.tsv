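# Novel miRNAs reported from the radish CK/Cd200 small-RNA libraries
# lp = precursor length (nt); mfe = minimum folding free energy (kcal/mol)
name	mature	size	lp	mfe	reads_ck	reads_cd	log2fc	total_mature	total_star	loci
rsa-miRn1	UCGCUUGGUGCAGGUCGGGAA	21	141	-72.20	8263	9468	0.42	17731	199	1
rsa-miRn2	UGAAGCUGCCAGCAUGAUCUA	21	118	-48.00	1524	4358	1.74	5882	16	1
rsa-miRn3	AAGCUAGAGACUUAAAACAAG	21	139	-23.95	65	8	-2.80	73	19	1
rsa-miRn4	GCGUAUGAGGAGCCAAGCAUA	21	106	-49.30	1045	574	-0.64	1619	168	1
rsa-miRn5	GUGGUGACGGUGGUGGUGCGA	21	99	-36.40	5	0	-8.31	5	1	2
rsa-miRn6	CAGGGAACAAGCAGAGCAUGG	21	110	-46.10	3972	2741	-0.31	6713	1557	1
rsa-miRn7	AUAUACUGAAGUUUAUACUCU	21	208	-37.00	58	362	2.87	420	36	1
rsa-miRn8	GUAUGAGGAGCCAAGCAUAU	21	107	-46.60	1137	563	-0.79	1700	198	1
rsa-miRn9	GUACGACGAAGAUGAGCCGACA	23	110	-19.60	36	25	-0.30	61	5	3
rsa-miRn10	UGGAGGCAGCGGUUCAUCGAUC	22	140	-45.70	378	452	0.48	830	2370	1
rsa-miRn11	GCUCAAGAAAGCUGUGGGAAA	21	147	-39.04	0	242	14.18	242	72	1
rsa-miRn12	AAACUGCCUAAACAAACAUAUC	22	171	-40.44	56	38	-11.87	59	14	1
rsa-miRn13	GCUGGAGGCAGCGGUUCAUCGAUC	23	142	-46.80	827	2326	1.72	3153	300	1
rsa-miRn14	AGAUGACAGUGAGGCUUCUUA	21	108	-18.20	0	28	11.02	28	1	4
rsa-miRn15	CCCGCCUUGCAUCAACUGAAU	21	137	-66.30	222	34	-2.48	256	19	1
rsa-miRn16	UCGCUUGGUGCAGGUCGGGAC	21	142	-73.60	12154	14602	1.31	37886	3276	1
rsa-miRn17	UUGGACUGAAGGGAGCUCCUU	21	201	-86.70	8	0	-8.99	8	1	1
rsa-miRn18	CGCCUUGCAUCAACUGAAUCA	21	108	-56.70	1721	1423	1.71	6544	170	1
rsa-miRn19	AUGGAUGUAUGAUAUGAUGGA	21	136	-41.40	0	21	10.60	21	3	1
rsa-miRn20	GGAAUGUUGUUUGGCUCGAAG	21	72	-20.00	10	27	1.66	37	1	1
rsa-miRn21	UCGGACCAGGCUUCAUUCCCC	21	133	-67.20	36853	53357	0.76	90210	436	1
rsa-miRn22	AAGCUGCCAGCGUGAUCUUAAC	22	101	-41.80	2638	3280	0.54	5918	2018	1
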