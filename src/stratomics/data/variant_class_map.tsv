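maf_classification	classification
Missense_Mutation	missense
Nonsense_Mutation	nonsense
Frame_Shift_Ins	frameshift_ins
Frame_Shift_Del	frameshift_del
In_Frame_Ins	inframe_ins
In_Frame_Del	inframe_del
Splice_Site	splice_site
Splice_Region	splice_site
Translation_Start_Site	translation_start_site
Start_Codon_SNP	translation_start_site
Nonstop_Mutation	nonsense
Silent	silent
3'UTR	utr3
5'UTR	utr5
Intron	intron
3'Flank	flank
5'Flank	flank
IGR	other
RNA	other
Targeted_Region	other
lincRNA	other
De_novo_Start_InFrame	other
De_novo_Start_OutOfFrame	other
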