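>TRBVS1|V|anchor=30
AGACGTAGTTCGTTCGTGCTTTTGGCTCATTGTAACTAGTGCCAG
>TRBVS2|V|anchor=30
GCTCTTCTCCAGCTGTTACATGTTCGACCTTGCTACGGTGTCGAT
>TRBVS3|V|anchor=30
TTGCCATACCGCTTAGTAGACCGTCATCGATGTGATAGAAGAGAA
>TRBVS4|V|anchor=30
CCACCTCGCACGCTGAGATCGGTTATATGTTGCATTGAAAAGAAA
>TRBVS5|V|anchor=30
TTTTAACAAGCTAATTGGTTATATCACGGGTGTCTCTGACACATG
>TRBVS6|V|anchor=30
GGTATGATGTTCTTTGTCATAATGTGCCCATGCATCCTAGTATAT
>TRBVS7|V|anchor=30
ATTATACCGACGCTGACGGGCCGCTTTGGTTGTATGGGATGTCCA
>TRBVS8|V|anchor=30
CACTAGCGAGCGGCCGCGGCACGTGGAAAGTGCGTGCGTCCGCGC
>TRBVS9|V|anchor=30
ACGTTGAATTGTAAGTTGTGGCCTCGACCATGTCACGTCTTTAGA
>TRBVS10|V|anchor=30
CCGTCGCCAGTTCAATGCGTGTAAAGTGTTTGCACCATCTTCGTG
>TRBVS11|V|anchor=30
TCCGCTAAGGCTAAGGACTAGGGGACTCGGTGTGGTTCGCGGTCT
>TRBVS12|V|anchor=30
CGCCGTAACTTTCGAGCGAACAACGGTGTTTGCGGACATAAAGCC
>TRBDS1|D
GGGACAGGGGGC
>TRBDS2|D
GGGACTAGCGGGAGGG
>TRBJS1|J|anchor=12
ATAGTCCCTAGCTTCCACGTTGTAGGT
>TRBJS2|J|anchor=12
ATCTATTTCCACTTTTAACAGGCTGAA
>TRBJS3|J|anchor=12
GTGATAGTGACTTTCCAGAGCTTCGTT
>TRBJS4|J|anchor=12
TTTGTGGATGAATTTCTTTACTGTCGT
>TRBJS5|J|anchor=12
ATAAGACACCCGTTCGGAGCGCGACAC
>TRBJS6|J|anchor=12
TCCCACCCACTATTTTCACCTTTGGAG
>TRBJS7|J|anchor=12
AAGAATCGTTGATTCTATTATTCCACT
>TRBJS8|J|anchor=12
AAGGTCGTCTTCTTTGTCGACTTTATA
>TRBJS9|J|anchor=12
GGTTTAAATTATTTCGGAACCCCCTAG
>TRBJS10|J|anchor=12
TCGCAGTTGAAATTTTCGTTAAGCCAA
>TRBJS11|J|anchor=12
TTACGTATGGCATTCTGACCGACAATT
>TRBJS12|J|anchor=12
GCTGATTTATGGTTTAATAACCCAATC
>TRBJS13|J|anchor=12
AGCTAGGATCGATTCCTAGATGGGTTC
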