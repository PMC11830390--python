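>IGHD1-S1*01
CAGAGAGATATATA
>IGHD1-S2*01
CCCCTGAGCACATCACCA
>IGHD2-S1*01
TTCAACTCCGGCGAGA
>IGHD2-S2*01
CTTGTTAACCCGAGCTTCGAA
>IGHD3-S1*01
GGGTTAAACGAC
>IGHD3-S2*01
CGAGATCTCCCCATCTCCTAACGG
>IGHD4-S1*01
GTTATCCTTAGATTGTG
>IGHD4-S2*01
CCCCCAACAACGTAATCGCG
>IGHJ3-S1*01
GGGGTCCGTGGCTTCGCGCCAGCTTGCGGGACACGGTCGGGCTTG
>IGHJ4-S1*01
ACTGGGCGTTGGACGACTAGAGTAGACGCTAGAGATACGCCT
>IGHJ5-S1*01
AACTTTCCGCTCATCTGGTATGATTACGGAGCACCGCGGGCTAGCAGA
>IGHJ6-S1*01
ATGCAACTTTTTAGTCCATGGTCTCGATCCCCCCTTGGCGCCTCGGCCACC
>IGHV1-S1*01
CAAACGGTTGCCTTAACCCTCGACATTCTCCTTTGCTCTACAGACGAGTGGATGCTTGTA
CCATTTCTAGGCGCATATATTTGGTATCCTCAGCGCCGTGGGTATGACGTCCTCGTCGGA
AATGCACACTGGGGTACACCAGGAACTGTGTGGGTCCTGATCGTAAGTCGCCGCCCTGGT
GCTGACCGGGCGAAGCAATTCCGTCCGGCTAAAAAGATGGTTGCTCAACATAGTATTTGC
CTGGTTGCCAGGTTGCGAGTGGTGCGCTTAAATATGTTTGGACCCTACTGTGCTAGG
>IGHV1-S2*01
CAAACGGTTGTCTTAACCCGGGACATTCTCCTCTGCTCTACAGCCGAGGGGGAGCGCGGA
CCATTCCTAGGCGCAGATATTTGGTATCCTCACCGCCGTGGGTTTGACGTCCTCGTCGGA
AATGCACACTGCCGTACACCAGGAACTCAGTGGGCCCTGATCGTAAGTCGCCGTCCTGGT
GCTGTCCGGGCGAAGCAATTCTATACGGCAAGAAAGATGGTTTCTCAACTTAGTTTTTGC
CTGGTTGCCAGGGTGCGAGTGGTGCGCGTAAATATTTTTAGACCCTATTGTGCTAGG
>IGHV3-S1*01
TTCACGGTTGCGCGAGGCCGCGTCGCTCGTCTTCGCGGTACAGCGAAGTGCATGCTTGTA
AGATTCCCACGCGCAGAACTGCTGCGGAAGCACCGCGTTGCATACGAAGGCGCCATCATA
AGTACACGGTGGGATGCCCGAGTATTTGCATGCACCCCGATCGTAAACCACTCTCATTCT
GCTGCCGGGACAACGCGATCCAATTTAGCCAAAAAGATGTTGCCGCAAGTTGGTATTTTG
CCGGATTCCAGTGTCGGACTGCTACCTCAAAAAATTTTTATACCCTATTGTGCGACA
>IGHV3-S2*01
TGCACGGTTGTGCGACGCCGCGTCGCTCGTCTTCGCTGTACAGGGAAGTGCATGCTTGTA
AGATTCCTACGCGCAGAACTGCTGCTGAACCACGGCGTTGCATATAAAGGCACCATCATA
AGTCCACGGTGGGATGCCCAAGTACTTGGATGCACCCCGATCGTAAGCCACTCTCCTTCT
GCTGCCGGGACTACGCGATTCAATTTCGCCAAAAAGATGGTGCCGCAAGTCGGTATTTTG
CCGGGTGCCAGTGTCGGACTGCTACCTAAAAAAATTTTAATACCCTATTGTGGGACA
>IGHV3-S3*01
TTCACGGTTGTGCGAGGCCGCGTCGCTCGTCTTCGCTGTACAGGCCAGTGCATGCTTGTA
AGATTCTTACGCGCAGAACTGCTGCTAAACCACCGCGTTGCATACAAAGGCGCCAGCATA
AGTCCACGGTGGGATGCCCGAGTATTTGGATGCACCCCGATCGTAAGCCACTCCCCTTCT
GCTGCCGGGACAACGCGATTCAATTTAGCCAAAAAGATGGAGCCGCCAGTTGGTATTTTG
CCGGGTTCCAGTGTCGGACTCCTACCTCAAAAAAGTTTTATACCCTATTGTGCGACA
>IGHV4-S1*01
CTCACGGTTGCTCCAACCCGCGACTCTAGACATCTTTCTACACCGGAGAGTATGTTTGCA
AGAGGCATACGTGCAGATCCTCGGCTGAACGACCCTAGTAGATATCAAGTCCCAATAGGG
ATCGAAGGGTGCCCTACCGCAGGCTCTGAACGGACCTCACTCGCACGTCAGTCTCGTTCA
GCGGCCTTGATGATGCCATTCCTGGGTGTTAAAAAGACGGTGGCGAAGCTTGGTATGCGC
CCGGGTTACAATCTGCGGGCGCTGCGCCTTAATATACTTGGACCAGATTGTCCGAGA
>IGHV4-S2*01
TTCACGGTTGCTCCAACCCGCGACCCTAGGCATCTTTCTACACAGGTGAGGATGTTTGCA
AGAGGCATACGGGCAGATCCTCGGCTGAACGACCCTAGTAGATATCAAGTCCCAATAGGG
AAAGAAGGGTGCCATACCGCAGGGTTTGGCCGGACCTCACTCGCACGTCACTCTCGTGCA
GCGGCCTGGATGATGCAATTCCTGGTTGTTAAAAAGATGGTTGCGAAGCTTGTTATGCGC
CCGGGTTACAGTCTGCGGGCGCTGCGCCTTAATATTCTTGGTCCCGATTGTCCGAGA
>IGHV5-S1*01
CACAAGGTGGCGCCAACCCCGGACATTCCACGGCGTACTCCGATGGAGTTAACGCACTCA
GAATCCAGATTCGCAGATTTTCGGATGGACAGTCGCAGTGGCTATAGTGATGCTGTAGGA
GACGCACGGTGCCACACTCCAGGACTTACATGCACCCCAATCGCAGCTCCATCTCCTACC
GCTGCCCGGACTAGGGACTCCATCTCAGCCAAAACAACGGTTGCGCAACTTGGTTTGGGT
CCACGTTCAAGGCTGCGTTCCGTGCGCGTGAATATTTTTAGACCCTATTGTGAGAAA
>IGHV5-S2*01
CACACGGTGGCGCCAACTCCGGACATTCCCCTGCGTTCTCCGACGGAGTTCACGCACCTA
GCATCCCGACTCGCAGATTTTAGGTTGGACAGACGCAGTGGTTATAATGTTCCCGTAGGA
GACGCACGGTGCCACACCCCAGGACTTGCATGCACCCCAATCGCAGGTCGATCTCCTACC
GCTGCCCGGACTAGGGACTCCATGTCAGCCAAAACGACGGTGGCGCAACTTGGTTTGGGT
CCAGGTTCAAGGCTGGGTTCCGTGCTCGTGAATATTTTTAGACCCGATTGTGAGCAA
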