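# Cadmium-responsive novel miRNAs: raw counts per library (CK, Cd200).
# Normalization denominators are the library clean-read totals
# (15,779,290 and 13,495,250; see radish_library_stats.tsv).
name	count_ck	count_cd	printed_log2fc	printed_regulation
rsa-miRn3	65	8	-2.80	down
rsa-miRn4	1045	574	-0.64	down
rsa-miRn5	5	0	-8.31	down
rsa-miRn11	0	242	14.13	up
rsa-miRn14	0	28	11.02	up
rsa-miRn15	222	34	-2.48	down
rsa-miRn17	8	0	-8.99	down
rsa-miRn19	0	21	10.60	up
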