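# Sequencing-read statistics for the radish CK and Cd200 small-RNA libraries
# and the mixed degradome library (unique = distinct sequences)
library	metric	total	unique
CK	raw_reads	15983864
CK	clean_reads	15779290	4615663
CK	mapped_reference	7396733	720362
CK	known_mirna	1771311	31280
CK	unannotated	10536202	4446875
Cd200	raw_reads	13664651
Cd200	clean_reads	13495250	4071113
Cd200	mapped_reference	6592663	595759
Cd200	known_mirna	1152100	28788
Cd200	unannotated	8038038	3862789
degradome	clean_reads	25741860	8037807
degradome	mapped_reference		6287867
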