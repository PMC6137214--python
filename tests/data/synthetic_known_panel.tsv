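locus_id	unit	n_units	upstream_flank	downstream_flank
H1R17	CTTT	17	GCGACTGTCCAGTTCTGCTGAATGA	GATCTCCAACAGTGGATCGATAACG
H2R13	CTTT	13	GACTGTCCAGTGACAGAACCGAGCA	GAAGTATCTGTGTATCGATTCCAAC
H3R15	CTTT	15	ACTCATGCTGCCTGTCCAGTGTTTG	GACCGTATCAGTGGGTCGAGAGATC
H4R14	CTTT	14	TTACTGTCCAGTGGAGGCCTTGGAC	TCCGACGCTTGACAGTGGATCGACA
H5R17	CTTT	17	CCCCCATAGACTGTCCCGGGGGAGG	ATCGGTCTTTCAGAGGATCGACTAG
H6R15	CTTT	15	GTGTCAACTGTCCAGTCAATCTCAC	ATCTTTTATACAGCGGATCGAGGGC
H7R16	CTTT	16	AACCAGGACTGTCCAGTCGCTAAGC	TGCTGACTTACACAGTGGATCGACC
H8R19	CTTT	19	CGGACTGATCAGTATGTCCCTAGAG	GAAAAGTCATTGGATCGAATCCAAT
H9R14	CTTT	14	GTAGCTAATTACACATGGTACCATG	AGGACACCTATAAATAATGAGTATT
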