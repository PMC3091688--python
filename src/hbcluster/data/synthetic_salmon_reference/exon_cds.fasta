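>alpha.exon1
ATGTCTTTTAGTAATGTACATTGGTTCCTGGTCATTTTACAGTCTGATGTTCGGGAGCTGGGTGATATTCAGGAAATCTTCTGTACCGAGTGC
>alpha.exon2
ATGTGTATGACCGGGATCCCACCGTCGTTCCACCACTATAGAATTACATACAGACCGCTAGATATGTCCAATGTGCAACATTGGAATAAGCGTGCACACCACAGAGCTCAGCGAATGAATGACATTTTCACGGGCCAGCACGCAAGATGTCGAGAGTTCACGTCGTGGCCTCCGATGCAAAAGTGGATGTTTCCAATCGATCAG
>alpha.exon3
GGCAGTCAACTGTTTCGTAAAAGACTCCAGCAGAACCGATGCGGGAATATTCACAATTTAATGGTATACATGATAAAATTTTCGCAAGTGAACGGAGCCAGTCAGTTAACGGTTTGGGGAGACCAGTGGTAC
>beta.exon1
ATGGGCTTTCACTTTATGGGGCTAATCATTGACTCTTTCATTATGAATACTTACTGGACTAACTATACGAACTTTTGCGCGTGCGGTGCA
>beta.exon2
TGGCCTCAAGGTAGCTCAGCAGATAAGGCGCACACAAAGTGCAACTTCTGGACTGAGTATTGCTGGCATTCATGCGAGAACCTAGACTATAAACCGCAGATGCCTAGGATGCAAATGGATGAATATTCAAAAGCGCCCTTCCATATCGCCATGCACGGCAACCCTTCGCTTCCTGAAGGGTATTGCCAGGGGCATTGTAGAATACGTTCCCAAGACCATTGC
>beta.exon3
CCGGGTCCATCCATGAATAACTGCACGATGTATGAAAGATGTATCTTTTATTTTGAGAACTATACACGAATGAACTGGTTCTATGTACCACCTCCAATACCAGGTAAATCAACCAACATAAGGGAGGAGCAT
>beta_nonbohr.exon1
ATGGGCTTCCACTTCATGGGGCTCATAATCGACTCATTCATTATGAATACTTATGAGACGGCCTATACCAATTTTTGCGCATGTCTAGCA
>beta_nonbohr.exon2
TGGCCGCTGGGAAGCAGCGCGGACAAAGCACATTCGAAATGTAACACATGGACAGAATATTGCGATCATAGCTGCGAAAACCTCGATCGCAAGCCCGCAATGCCTCGAATGCAAATGGATGAATATCACAAAGCGCCGTTCCACATTGCTATGGCAGGGAACCCCAGCCTGCCCGAGGGATACTGTGCGGGCCACTGTCGAATACGGAGCCAGGATCATTGC
>beta_nonbohr.exon3
GACGGTCCAAGTATGAATAACTGTACGATGTATGAGAGATGTATCTTCTACTTCGAGAACCAAACACGAATGAATTTCTTCTATCATATGCCACCGATCCCAAGCAAGAGTACGAACATACGCGAGTTC
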