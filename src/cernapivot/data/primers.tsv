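id	forward	reverse	product_length_bp
FKBP5	AGCAGGGAGAGGATATTACC	TCATCGGCGTTTCCTCAC	87
CDON	CTGCATCAGAGACATCAGTCTA	GGTCCTCATCCGTTTATATTCG	98
PGAP1	CCAGATAAATCAGTTGACCCAC	CTTCAAATGCAGCACTGTAAAG	112
NEAT1	TAGCATGTTTGACAGGCGG	AGTTTAGCGCCAAACCTAGA	126
SNHG3-203	TTTGCTTATCAGCTCTTTGTCA	AGAGGTAAATCCTGACCAACT	86
TERC-201	CCTAACTGAGAAGGGCGT	GCTCTAGAATGAACGGTGG	116
SNHG12-202	TGTGACTATGGACCTATGGAG	GCATGCTGTTGTTTCTACCTAA	89
ENST00000610809	CACAAAGGAACGTAGACAAATG	ATGAGGTGGGCTTGTTTGAA	80
ENST00000443132	CTTTGATCTTCTGTGATAGCGA	TTCTTCCAAGGGGCAGGATAA	107
ENST00000619523	ACAGATCATCCTGTCCTCC	ACACACTCTTCCAAGCAC	86
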