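id	role	substrate_category	substrate_subtype	source_note
mtaB_1	MtxB	methyl_O	mtaB methanol	synthetic stand-in, mtaB family
mtaB_2	MtxB	methyl_O	mtaB methanol	synthetic stand-in, mtaB family
mtaB_3	MtxB	methyl_O	mtaB methanol	synthetic stand-in, mtaB family
mttB_1	MtxB	methyl_N	mttB Pyl trimethylamine	synthetic stand-in, mttB family
mttB_2	MtxB	methyl_N	mttB Pyl trimethylamine	synthetic stand-in, mttB family
mttB_3	MtxB	methyl_N	mttB Pyl trimethylamine	synthetic stand-in, mttB family
mttB-nonPyl_1	MtxB	methyl_N	non-Pyl mttB quaternary amine	synthetic stand-in, mttB-nonPyl family
mttB-nonPyl_2	MtxB	methyl_N	non-Pyl mttB quaternary amine	synthetic stand-in, mttB-nonPyl family
mtbB_1	MtxB	methyl_N	mtbB dimethylamine	synthetic stand-in, mtbB family
mtbB_2	MtxB	methyl_N	mtbB dimethylamine	synthetic stand-in, mtbB family
mtmB_1	MtxB	methyl_N	mtmB monomethylamine	synthetic stand-in, mtmB family
mtmB_2	MtxB	methyl_N	mtmB monomethylamine	synthetic stand-in, mtmB family
mtoB_1	MtxB	methyl_O	methoxy	synthetic stand-in, mtoB family
mtoB_2	MtxB	methyl_O	methoxy	synthetic stand-in, mtoB family
mtoB_3	MtxB	methyl_O	methoxy	synthetic stand-in, mtoB family
mtsA_1	MtxB	methyl_S	mtsA	synthetic stand-in, mtsA family
mtsB_1	MtxB	methyl_S	mtsB	synthetic stand-in, mtsB family
mtsD_1	MtsFused	methyl_S	mtsD/F/H	synthetic stand-in, mtsD family
mtsF_1	MtsFused	methyl_S	mtsD/F/H	synthetic stand-in, mtsF family
mtsH_1	MtsFused	methyl_S	mtsD/F/H	synthetic stand-in, mtsH family
mtaC_1	MtxC	methyl_O	mtaC	synthetic stand-in, mtaC family
mtaC_2	MtxC	methyl_O	mtaC	synthetic stand-in, mtaC family
mtaC_3	MtxC	methyl_O	mtaC	synthetic stand-in, mtaC family
mtaC_4	MtxC	methyl_O	mtaC	synthetic stand-in, mtaC family
mttC_1	MtxC	methyl_N	mttC	synthetic stand-in, mttC family
mttC_2	MtxC	methyl_N	mttC	synthetic stand-in, mttC family
mttC_3	MtxC	methyl_N	mttC	synthetic stand-in, mttC family
mttC_4	MtxC	methyl_N	mttC	synthetic stand-in, mttC family
mtbC_1	MtxC	methyl_N	mtbC	synthetic stand-in, mtbC family
mtbC_2	MtxC	methyl_N	mtbC	synthetic stand-in, mtbC family
mtbC_3	MtxC	methyl_N	mtbC	synthetic stand-in, mtbC family
mtmC_1	MtxC	methyl_N	mtmC	synthetic stand-in, mtmC family
mtmC_2	MtxC	methyl_N	mtmC	synthetic stand-in, mtmC family
mtoC_1	MtxC	methyl_O	methoxy mtxC	synthetic stand-in, mtoC family
mtoC_2	MtxC	methyl_O	methoxy mtxC	synthetic stand-in, mtoC family
mtoC_3	MtxC	methyl_O	methoxy mtxC	synthetic stand-in, mtoC family
mtaA_1	MtxA	methyl_O	mtaA	synthetic stand-in, mtaA family
mtaA_2	MtxA	methyl_O	mtaA	synthetic stand-in, mtaA family
mtaA_3	MtxA	methyl_O	mtaA	synthetic stand-in, mtaA family
mtaA_4	MtxA	methyl_O	mtaA	synthetic stand-in, mtaA family
mtbA_1	MtxA	methyl_N	mtbA	synthetic stand-in, mtbA family
mtbA_2	MtxA	methyl_N	mtbA	synthetic stand-in, mtbA family
mtbA_3	MtxA	methyl_N	mtbA	synthetic stand-in, mtbA family
mtoA_1	MtxA	methyl_O	methoxy mtxA	synthetic stand-in, mtoA family
mtoA_2	MtxA	methyl_O	methoxy mtxA	synthetic stand-in, mtoA family
mtoA_3	MtxA	methyl_O	methoxy mtxA	synthetic stand-in, mtoA family
ramA_1	RamX	ambiguous		synthetic stand-in, ramA family
ramA_2	RamX	ambiguous		synthetic stand-in, ramA family
ramA_3	RamX	ambiguous		synthetic stand-in, ramA family
ramA_4	RamX	ambiguous		synthetic stand-in, ramA family
ramM_1	RamX	ambiguous		synthetic stand-in, ramM family
ramM_2	RamX	ambiguous		synthetic stand-in, ramM family
ramM_3	RamX	ambiguous		synthetic stand-in, ramM family
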