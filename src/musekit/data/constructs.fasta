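>iKey-64 plasmid=pBZ38
TTTTTTTTTTCGGAGCTGAGACCGAACGTAGGCTTCGGCACTGTTAGAAGATATCAACAATTCACGTATG
CGCGTGGTAACTTGTCTTTTGATTCACTGCCATTCTGCGGAGCTCCCATTCAGATCCACCTGGAGGGGAA
AGATAGTTTATGTCACACAGTACTAACAAAAACCCGGGTTTAGTCTAGGCGGTCCTGCCCCGTTTTTTTT
TT
>DNA-1 plasmid=pBZ27
TGGCCACGATCCATGCTAACGTCTCTGCGTAGGGATGAATCCCGTTTTGAACTCGTTCCTACTGACGGAC
GAGCTGATAGGTAGCCGAAGTAGTGATACGATCCACACATGCCATCATTGCATACTCGTGCATTCAATGA
TGCATAGTCACGTAGTCCATATGGTAATGGTGATGTCAAGTCACATGTCAATACTCGTCACTAGAACTGA
GCGCGATGACTGGCGAGCTGGTGCGCTCCCGAGGCTGGTCGAGCGACTAAGTTGAATGCGCAGACCGATC
GAGACGACTCTAGCGCTGGAATAAATCAGAATAAAGA
>DNA-2 plasmid=pBZ28
CCCACCAATACTGCCAATAGACGGTACTGTACACCCTGTTTTACAGCAACGGGAAAGGAGGATCACTTTC
TACAATTGTGTGCTGGACTGACAGTCGCATATCCACACATGCCATCATTGCATACTCGTGCATTCAATGA
TGCATCTACACGTAGTCCATATGGTAATGGTGATGTCACTACACATGTCAATACTCGTCACTAGAACTGA
GCGCGATACGACTCGCCCATAGGGTTCGCCGGCTCGCACTGACTACCTTACGCTCTGACCCAGATCGGAG
CCGGCCGCATGACCCCTGTGATATAATACCGTTCATC
>n1 plasmid=pBZ29
TAATACGACTCACTATAGGGACAGTCTAGTGCAGCAGTCAGTACGAGTCTCATGAGTGTAGGATGCATGA
TCATGATTCTGATCTAGTCCAGCAGTAGAGTCGTCTCGATCGATCTGTGCATCGTCAGCGATATTCGACG
TAGTCGCTCGACCTGACTCGTGAGTGCAGCTACGTGTCAGTCATCCACTGTTGCCATATATGCAGACGGC
ATAGTATGCGTGTATGCGTCGAGAGATCATCCAGTTCTTGACGTTAGTTACAAGATTGGCCACGATCCAT
GCTAACGTCTCTTCCACCTTTCCCAAAAAGTAACACCGACTGATCGCGCATACGGCAACAGTGACTCTCG
ACTACCATAGTAGTGAGATGGTGGATTACGATCGCGTGATCTGAGTATCATTGATCTATAGTGGATTGAC
TGATGATCGTACTGTCGTACTGACTCTGACGTCGATCTCAGGTCATATTACTCGACAGTTGCTAAGTCAG
TCATCGTCATACGATGCCGCTGAGCAATAACTAGC
>n2 plasmid=pBZ30
GCTAGTTATTGCTCAGCGGCATCGTATGACGATGACTGACTTAGCAACTGTCGAGTAATATGACCTGAGA
GCTACTGATCTGACTAGCTAAGCTTGCATGCACGTCATGATCCACTATAGATCAATGATACTCAGATCAC
GCGATATCGACGTTGACTAGTCAAGCTAGATCCACATATGCTGTATGTGCGTAGTCGATGTCATGACTAT
GTTTTACAGCAACGGGAAAGGAGGACCGTCTATTGGCAGTATTGGTGGGATCTTGTAACTAACGTCAAGA
TAGGGATGATCTCTCGACGCATACACGCATTAGATGCCGTCTGCATATATGGCAACAGTGGATACGACTC
GATCATCGAGTTCGCATGCTAGCACTGACTACGTTACGCTCTGATCTCAGACGATAGTCAGATCGGAGTC
AGCTGCATGACGACAGTGCGATGCTAGCGTTGATCTCATGCATCCTACACTCATGAGACTCGTACTGACT
GCTGCACTAGACTGTCCCTATAGTGAGTCGTATTA
>n3 plasmid=pBZ31
TAATACGACTCACTATAGGGACAGTCTAGTGCAGCAGTCAGTACGAGTCTCATGAGTGTAGGATGCATGA
TCATGATTCTGATCTAGTCCAGCAGTAGAGTCGTCTCGATCGATCTGTGCATCGTCGACGATATTCGACG
TAGTCGCTCGACCTGACTCGTGAGTGCAGCTACGTGTCAGTCATCCACTGTTGCCATATATGCAGACGGC
ATAGTATGCGTGTATGCGTCGAGAGATCATCCAGTTCTTGACGTTAGTTACAAGATTGGCCACGATCCAT
GCTAACGTCTCTTCCACCTTTCCCAAAAAGTAACACACCATGACGTATCGACTACGCACATACAGCATAT
GTGGATGATCACTGACTGACTGAACTACGATCATGGTGTATGTGAGCGTGTATGTGCTCGTGACTGGAGA
AACGGCAACAGTGGATGATTGACGTACGACTGCTAGCTCAGGTCATATTACTCGACAGTTGCTAAGTCAG
TCATCGTCATACGATGCCGCTGAGCAATAACTAGC
>n4 plasmid=pBZ32
GCTAGTTATTGCTCAGCGGCATCGTATGACGATGACTGACTTAGCAACTGTCGAGTAATATGACCTGAGA
GTCAGTGCTCATGATGTCAATCCACTGTTGCCGTTTCTCCCTACACGAGCACATACACGCTCACATACAC
CATGATGACTAGCATGATCATCCACCGTGTATCTAGATCACGCCGGCATGATCTGATGACGATCATGACT
GTTTTACAGCAACGGGAAAGGAGGACCGTCTATTGGCAGTATTGGTGGGATCTTGTAACTAACGTCAAGA
TAGGGATGATCTCTCGACGCATACACGCATTAGATGCCGTCTGCATATATGGCAACAGTGGATACGACTC
GATCATCGAGTTCGCATGCTAGCACTGACTACGTTACGCTCTGATCTCGGACGATAGTCAGATCGGAGTC
AGCTGCATGACGACAGTGCGATGCTAGCGTTGATCTCATGCATCCTACACTCATGAGACTCGTACTGACT
GCTGCACTAGACTGTCCCTATAGTGAGTCGTATTA
>n5 plasmid=pBZ33
TAATACGACTCACTATAGGGACAGTCTAGTGCAGCAGTCAGTACGAGTCTCATGAGTGTAGGATGCATGA
TCATGATTCTGATCTAGTCCAGCAGTAGAGTCGTCTCGATCGATCTGTGCATCGTCACGGATATTCGACG
TAGTCGCTCGACCTGACTCGTGAGTGCAGCTACGTGTCAGTCATCCACTGTTGCCATATATGCAGACGGC
ATAGTATGCGTGTATGCGTCGAGAGATCATCCAGTTCTTGACGTTAGTTACAAGATTGGCCACGATCCAT
GCTAACGTCTCTTCCACCTTTCCCAAAAAGTAACACTGACTGCATTCGTGATCATCATGCCGGCGTGATC
TAGATACACGGTGGATTCAGCTACTAGTCGAATCATGACGTGAGAAGCATGAACGATATGAAGAAGTTAT
GTGGATAGCTGTCGACGTGATCGTATCGATGCAGTCCTCAGGTCATATTACTCGACAGTTGCTAAGTCAG
TCATCGTCATACGATGCCGCTGAGCAATAACTAGC
>n6 plasmid=pBZ37
GCTAGTTATTGCTCAGCGGCATCGTATGACGATGACTGACTTAGCAACTGTCGAGTAATATGACCTGAGA
GCTATCGATGACGTACTGATGTCATCATGATCCACATAACTTCTTCATATCGTTCATGCTTCTCACGTCA
TGATAACGCATCCACCATCTCACTACTATGGTAGTCGAGCTACACTGTTGCCGTATGCGCGATGTCAATT
GTTTTACAGCAACGGGAAAGGAGGACCGTCTATTGGCAGTATTGGTGGGATCTTGTAACTAACGTCAAGA
TAGGGATGATCTCTCGACGCATACACGCATTAGATGCCGTCTGCATATATGGCAACAGTGGATACGACTC
GATCATCGAGTTCGCATGCTAGCACTGACTACGTTACGCTCTGATCCTAGACGATAGTCAGATCGGAGTC
AGCTGCATGACGACAGTGCGATGCTAGCGTTGATCTCATGCATCCTACACTCATGAGACTCGTACTGACT
GCTGCACTAGACTGTCCCTATAGTGAGTCGTATTA
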