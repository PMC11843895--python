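>MGMT-752
TGACTAGGGGAGCGGCACCAGGAGGGGAGAGACTCGCGCTCCGGGCTCAGCGTAGCCGCC
CCGAGCAGGACCGGGATTCTCACTAAGCGGGCGCCGTCCTACGACCCCCGCGCGCTTTCA
GGACCACTCGGGCACGTGGCAGGTCGCTTGCACGCCCGCGGACTATCCCTGTGACAGGAA
AAGGTACGGGCCATTTGGCAAACTAAGGCACAGAGCCTCAGGCGGAAGCTGGGAAGGCGC
CGCCCGGCTTGTACCGGCCGAAGGGCCATCCGGGTCAGGCGCACAGGGCAGCGGCGCTGC
CGGAGGACCAGGGCCGGCGTGCCGGCGTCCAGCGAGGATGCGCAGACTGCCTCAGGCCCG
GCGCCGCCGCACAGGGCATGCGCCGACCCGGTCGGGCGGGAACACCCCGCCCCTCCCGGG
CTCCGCCCCAGCTCCGCCCCCGCGCGCCCCGGCCCCGCCCCCGCGCGCTCTCTTGCTTTT
CTCAGGTCCTCGGCTCCGCCCCGCTCTAGACCCCGCCCCACGCCGCCATCCCCGTGCCCC
TCGGCCCCGCCCCCGCGCCCCGGATATGCTGGGACAGCCCGCGCCCCTAGAACGCTTTGC
GTCCCGACGCCCGCAGGTCCTCGCGGTGCGCACCGTTTGCGACTTGGTGAGTGTCTGGGT
CGCCTCGCTCCCGGAAGAGTGCGGAGCTCTCCCTCGGGACGGTGGCAGCCTCGAGTGGTC
CTGCAGGCGCCCTCACTTCGCCGTCGGGTGTG
>MGMT-G4
GGGCCGGGGCGCGCGGGGGCGGAG
>MGMT-G4-mut
GTGCCGGAGCGCGCGGAGGCGGAG
>MGMT-C
CTCCGCCCCCGCGCGCCCCGGCCC
>MGMT-ds1-f
GGTCCTGCAGGCGCCCTCACTT
>MGMT-ds2
CTCCGCCCCCGCGCGCCCCGGCCC
>non-specific-control
CTGAATACTACTTCCTACCCCTTACCTGAT
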