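>IGHV1-1*01
ATCATGAGACTGTCACGTTTTACGGATGAGGAAATTGTTTCAACACAATGGAATAACCCC
AGCCCAGGGCAAGGCAGCACTCCGGCGACGGAGCAGTCCACCCATTTATTGGCACGCGGT
CTCCCTTCCGATGACACCAACGGCTCCGCCCATCGGGTTTATTGGGTTTTGTGGAAGCTG
TCGATCACCAGCCTAGGCAAGGGTAAGGGTGCTAAATGCAGGACTGCGAGGAACAAACGT
TCTCTGCGACTAGGAGGTCCGTGGCGAGATCCCGTGAAGATAAACCTAGAAGATTGGATC
ATCAGAGTGTGT
>IGHV2-1*01
ATGACCAGGCCCTATCGAGTTGTTATGGGTTCTAGATTTACAGCGCTGGATGACTATGCG
ACTCTCCCGATTCTGGTTATCAAGGTATCGCGTTATTCGCATGCTTTCGCCAGAAGGTAT
TTAATTCGCATGTACTGTCGAGAGAGAGAAAACCATGGGTGGTTACCCCTGCAAGTGGAA
AAACTGACACCCACTTGGCAAGTTTGTGTAGACGCCAGATGGTACCTGTATATCCTGTGC
CCCCGGGACAGGCCAGGATTTAATTTTAAGCTGGAGGAAACCTTTACGCAGTTGACGATC
CAGATCTTGTGT
>IGHV3-1*01
CAGACTATTTTAGTAGAGAAGCTGGTCGAGGACAGGATTGGGCGTTGGAAAAGAGCGGTA
TGTCTGTCCTTTACGGGGTGGGACCTCCAC......TCCTTTTTGTACCTTAGGACAACG
CATTTTTATACAATCCGCATACTTATCCATGATGGGTCACGTCACGCGTTCGGGTCATCA
ATCCAGTCATTGGCCATAATTCGCGTCCCATTAAGGGGGAAGAACTTTCCACTTTCAGTT
CGGCACATGGCACGCCCCTTGAGGAATCCTTACTTGACTCAACTTGCGGCTAGCGTAAGC
GTCGATGGTTGT
>IGHV4-1*01
GAGTCTCATTTGATATTTGCGCTAGGCGGGACTCCGCCCCGCATTGTCTTTAGTTTACGT
TATTTATCAACGCGTCCTGATCCTACGAGACTCCCGAATTCCCCCTCCCGGTTTCACGTT
AAAGGCTGCAACGACGAGACAATCAAGGGTTCCAAGTCTTCCTTGTCCAATGGCAGGGAA
TCGTATCGTGTACAACCCAGAGCCAAGCAGTGCCATCTTGGCAATCGAATGTGTTTGGGC
AGTCACAGCAATGCCTACCGTCGCTTACGTTATTGGTATTCCACCGACAGTGCGCCTGTC
AAGCGCATGTGT
>IGHV5-1*01
CCATGGAGTATACCTTACCGGTTACTAACTGCCAAATGTTTCCCTAAAGCGGCGTTTAGC
CTATGGACTAGCGGGCCAAAATGTCTGTGGGGGTCTAAAAAGAGTAGCGATATCGATATC
CGCCTTGTGTTCCAAACCCTTGAACAGTTCGACCGTGCTAACAGGTTACCACCCCATCAC
ATAATTCGTTCTGGCAAGCACCACATTTGCGCTGACGTCAGGGTGATGAGAACTAGAGCG
CTGACGGGGCGAAGTGGGAACTTGCCACTGGCCGCGCGGGGGCGAGGAAAGGACTGCCTA
CGTCTCAGGTGT
>IGHV6-1*01
TCCGACTTTAAGGTTAGATTCGGCCAATGGCCGACACGGCTTTCCGACGAATTGCTTAAG
GGACAACACTTGGACCAGGGCTTACCTAAGTTA...TTCAAAGAGCATAGACATGCTTGC
TACGAGCCGTCTGAGTGCGATAAAGGTTGTGCCCTTCTGAGAGCAGATTTTGCATTA...
CGTTCTTATATACCTCCTCCTATGAATCGTATCAAACATCTTTTCATGCCAGTCGCTAGG
GTGCGGACAGTCAGCGTAAATTCACAATGTACTCGTCGGACAGTTCCGCGCTTACCCGGC
GGTGTGACATGT
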