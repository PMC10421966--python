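# SYNTHETIC stand-in pocket definition: 34 (chain, residue) positions
# in the style of an MHCII binding groove; regenerate real ones with
# mhc2tx.pseudoseq.extract_pocket_positions on a peptide:MHCII structure.
A	10
A	15
A	17
A	18
A	26
A	27
A	33
A	38
A	42
A	49
A	50
A	54
A	61
A	65
A	67
B	2
B	6
B	9
B	11
B	12
B	13
B	19
B	30
B	37
B	40
B	41
B	43
B	49
B	53
B	54
B	61
B	65
B	89
B	92
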