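# SYNTHETIC stand-in allele -> 34-mer pocket pseudo-sequence table
# (illustrates the format; not the experimentally derived sequences)
HLA-DRB1*01:01	GLNFAFNYYPCFNNHMIPATGVCSRGHGIACCGA
HLA-DRB1*03:01	QMCTWFAFMILCYATFINFFRQIAHLEDWYCLNE
HLA-DRB1*04:01	GDMARRCRREPHDRDAHAHCCINQKNGQIHMLHR
HLA-DRB1*07:01	IMMTNGESIPRPYGFSPSQNNMFWSDFPFRGMNY
HLA-DRB1*11:01	SVVHVWMTFLGWAGHRHTHLAVHLWDSRISRAIC
HLA-DRB1*15:01	YYIPAVTTEMRGRRRLMPISEHWYWGFFLGSNLL
HLA-DQA1*01:02/DQB1*06:02	FMPIDMWRAKPHTHKDAWDFWITAIMLMWVVIEI
HLA-DPA1*01:03/DPB1*02:01	MHSLENNFNGCYASFPYPCYYWMAMWHRDNFQRN
H-2-IAb	WVRVAFQECDFWFEECSPYMHYIVMSMLVWYAMK
H-2-IAg7	YECFFVGFNCCMDKIVFMYRAVKFVMCPWYCAPR
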