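chr1	4186	4234	CTTT_12_plain	0	+
chr1	4703	4743	CTTT_10_plain	0	+
chr1	4943	4983	CTTT_10_plain	0	+
chr1	7651	7699	CTTT_12_plain	0	+
chr1	9793	9861	CTTT_17_motif	0	+
chr1	10955	11007	CTTT_13_motif	0	+
chr1	12520	12576	CTTT_14_plain	0	+
chr1	12982	13042	CTTT_15_motif	0	+
chr1	14038	14102	CTTT_16_plain	0	+
chr1	15699	15751	CTTT_13_motif	0	+
chr2	1559	1623	CTTT_16_motif	0	+
chr2	3735	3795	CTTT_15_plain	0	+
chr2	7348	7416	CTTT_17_plain	0	+
chr2	9461	9505	CTTT_11_plain	0	+
chr2	10419	10491	CTTT_18_plain	0	+
chr2	13600	13644	CTTT_11_plain	0	+
chr2	14240	14296	CTTT_14_motif	0	+
chr2	14590	14650	CTTT_15_motif	0	+
chr2	15190	15242	CTTT_13_plain	0	+
chr2	15748	15820	CTTT_18_motif	0	+
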