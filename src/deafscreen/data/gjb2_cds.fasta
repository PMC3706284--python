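>GJB2|CDS|offset=0
CGCTAGCCATAAGTAAGTGTCTTGAGTCCACCGAGAGGTTTCTAGGCCCTGTGTGATCCGGAATTATAGA
TCGCCCATGGGGAAGATCATAGTGCGGGCGTGGATCACGTGCCGGGATGAGAAATAGCATTGAAATCGCC
GTACTGATACATCTAATAGCTTTAAACGCCGACTCCGCGCACGTGGAAGGATTGTCCCGCACAGTATTAC
CCTAGCAGCATGTAAGATCTTTCACAAGCGCTGCTCCTCCATCTTGCATGGGTTATAAGGTAGTACGGCT
ATTATGAATGGAGCCAACATTGATATCAAATGGCTCAGGTGAACAGGTTTTAGCTTTCAGATGGACCCAC
ATCAGCTGCTAAAATTTCCCTGTATGGGACAATGTCTACGCTAGCCAGACAGTGAGGAGTTCAGGGGGCT
CTCGTATTATGCCCCGGCTCCACCACCAGGGGGGAATCCACCGACTGTAGAAGATTCGTTTAGCCAGGGT
AAAGTTTCACTATTATAGAGCGACCGGCGCGGACAGTCAATCGGACTGTCGTTTACTCCCTCGGCAGTTA
AAAGCCGAGGTGGGCGTTCAAGTAACCTACACCGAGCTATGGCATCTTCCAGGGCAGAGTTATGCCTAAT
TTGCTCTTATGAGCGAACACCATCACTCCTCTACGAGGCTTTCAGTTG
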