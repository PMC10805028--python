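name	category	methyl_equivalents
methanol	methyl_O	1
syringate	methyl_O	2
trimethoxybenzoate	methyl_O	3
apocynin	methyl_O	1
monomethylamine	methyl_N	1
dimethylamine	methyl_N	2
trimethylamine	methyl_N	3
glycine betaine	methyl_N	3
choline	methyl_N	3
trigonelline	methyl_N	1
methanethiol	methyl_S	1
dimethyl sulfide	methyl_S	2
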