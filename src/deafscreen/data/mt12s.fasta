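>MT12S|12S_region|offset=600
CGTAATTCAGCTCTGCATATGCAGATCGCTTTGCGTGGTTGCGGGCCTCAGCTAGTGATTGGACGACAAA
TGATGGAGAATAGATTATCAGACCGCGCGAACCCATAGGCTATACCCCCTCGTGGAGTCGGGATAGAATT
TCGCCGAGCAGCCCCCCTCTATGTACACCCCACCTGCAACGGGCACGATTAGAATAGACCAAGTCCGGCT
TCCCCAAACGACTCACAGCTCACCGGCTGTCATCCCTTCGATTAAACTTTTTCACCCGCTTAAAAGTGGA
CGAAGTCGCAACAGCCCAACATAGCCGGTGCAGGAGCTGTTCATGTGCTTACTTAGTAGTGTTTTAGGAC
AAATAAATTGTTTAATATCATCAGAGTACGTCACGTTCATGTACTGCGTGCATTTTCACACTAAGGCATG
AATAATTTCACTCCAAACGTACTCGCACCAACACACGACCTCGAACCTCTAGTTTGAGGATAGATTTCTC
AAACTGGGGGCTTACGTCTCTCTCTGGTTCGTGGCGCTAACAAGTTAAGATGCTTCAAGTGGGGCGCTGA
TTTGATAGCCATGACTCTAAAAATGATCATTTGTGCCTAGCTATTGTTGTTATCCAAAGGAAAGATATAT
AGCAGTTCCTCTTTCGATGAGAACTGGATTCTCCAACACAAAGCCCCTCTAGGGGAAAGGAGCCCTAACT
ATTGAACATGAGACATAACCGAGTTTATCCGTTCGTCAGGCTCCAGGTGTTCGAAGGTCCCTCATTACAG
CTATTCGCTATAGAGTATTGTCCGAACAGGAGCGTCATGTGCGGGACAAGTACAAGTAAAGTGCAGGAGT
CAGCTCCCTCTGGCAATGGCCCTGCATGGCTACACGAACGCCTGTGCGATAACCCAGAACAACTTGCTTC
GAGAACCTCTAGGGTTCTCGTTCTTGGTACAAATAAAATCAAAGATCCGCCTCGGTACATAGACGTTATC
TCGGAGTAAATTTCCGCGGAATCATATACAGCTATAACTA
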