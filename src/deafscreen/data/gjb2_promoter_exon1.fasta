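>GJB2_EX1|promoter_exon1|offset=0
CAATAGGGGCGCCGGCTTAGGTGTCACTTGCGACACAAAGAATCCCTAATGACGCCTAAGTGGCCAGTCA
GGCATTCCGTCGAGGCAAGGAACTATCAATGGCGGACAACACGGTGATGCCCTCACCCCTTTCGCCGTCA
CCAACTGCCGAAACGATCTTTGAGCGTCCTCCCTATCTCCATGTTACTTATATGTCACCAAATCAACCGG
GCACACGGCGGCAGTTCGCTTTGACACGAAATACAGTCACACGGGCCTAAATGTTGGCCAGGAATACCGG
CCCTGTGCGGCTCCATCAACCTTAGACCTTTACGGATAGG
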