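>IGHJ1*01 fr4_start=9
CCCACTGACCCAGTGCACCGATTCCGTACGCACGATATCGATGGTTGT
>IGHJ2*01 fr4_start=9
AGCTTTTTGCGATTAAAGTTTATTTACGCACTAGGGTGTCCCAGAAAC
>IGHJ3*01 fr4_start=9
TCATTACACGATGCGCTCTCTGCCATTGGGGCTTGGTGGGTTTTTGAA
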