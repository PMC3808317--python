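# Known miRNA families and per-library read abundance, radish roots
# CK = control library, Cd200 = 200 mg/l CdCl2-treated library
family	group	members	reads_ck	reads_cd
miR156	conserved	13	291882	175380
miR158	conserved	9	114972	2904
miR159	conserved	4	2081	1233
miR160	conserved	2	45	122
miR162	conserved	2	1861	742
miR164	conserved	8	54932	36291
miR165	conserved	4	6986	1707
miR166	conserved	11	189669	57169
miR167	conserved	7	2628	12794
miR168	conserved	3	72829	61084
miR169	conserved	4	783	604
miR172	conserved	3	2103	1933
miR319	conserved	1	7241	1572
miR390	conserved	3	11993	3748
miR391	conserved	2	2157	1228
miR393	conserved	2	30	224
miR395	conserved	4	210	477
miR396	conserved	2	950	21753
miR397	conserved	1	3252	3013
miR398	conserved	1	164	753
miR399	conserved	2	23	55
miR408	conserved	5	417843	201889
miR403	non-conserved	3	1168	659
miR824	non-conserved	2	1178	568
miR825	non-conserved	2	115	42
miR827	non-conserved	2	36	472
miR854	non-conserved	1	485	145
miR857	non-conserved	1	1598	3162
miR1023	non-conserved	1	5	8
miR1442	non-conserved	1	183	26
miR2111	non-conserved	1	6	32
miR5021	non-conserved	1	15	76
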