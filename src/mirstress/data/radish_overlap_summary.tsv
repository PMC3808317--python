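# Common and library-specific sequences between the CK and Cd200 libraries
class	unique	total
all	7703916	29274540
shared	982860	20458468
CK_specific	3632803	5042275
Cd200_specific	3088253	3773797
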