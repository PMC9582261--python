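>IGHM
AAAGGACCTACAACCCGGGGTGCTATCCACGATGCCGGGTTTTGAAGAGGCATGTCTCCG
GTCGTTCGCTAATACCGCGGTCCGTTGGACACTGTGTAT
>IGHG3
CGACTCACGCAGAGCTCAACGGGCTACGTCCGTAAAATATGATTCAGCCACGATATCCAG
ATTGTACATTGGCGCCCGCTTTTAGCACGACTAATCAAT
>IGHG1
CCTCATCAAGGCATTCGCAGCCTGGAGTTATTTACACTCGAAACGCATTTTGACTGCACC
CCTTAGTCGCGAAAGCCATGCAGACGTCCGAACCGAACG
>IGHA1
TTATATTCATACGTTAAGGGCCATTAATCACGCGACAGTCAGCAACGATCGCCAACTCAT
AGCGTGGCGGTAGCATTAATCCGTACAAGCTTTTATCGA
>IGHG2
GCAGTTCAGCAGTCACATTCAGGCACAGCTGTCAATGTCGTAGCAGGCAAAGTTAGTAGA
TCTGACTCTTTAGCCTATTTGTAGACACCCGAGTTAGCG
>IGHG4
GATCGTTCTTTAAAAACGTCATTTTTCAGAAGGGTATCTATCATGATAGCGGTTGGATGA
TCACGAATGGCGATACAGCGGTGAGAACTGTTGTGCTTA
>IGHA2
TTCAGTCTCCCGATCAGCCGCTTGGTCCGAGCTGGTAGCCCCTTACTGAAGTACCGTGGG
GTTTATTGAGGACACCGTCCGGATCAGAGGTAAAAACGG
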