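name	sequence	start	end
1	AGAGTTTGATYMTGGCTCAG	8	27
2	ASYGGCGNACGGGTGAGTAA	100	119
3	ACTGAGAYACGGYCCARACTCCTACGGRNGGCNGCAGTRRGGAA	320	363
4	GGCTAACTHCGTGNCVGCNGCYGCGGTAANAC	504	535
5a	GTGTAGMGGTGAAATKCGTAGAT	682	704
5b	CAAACRGGATTAGAWACCCNNGTAGTCCACGC	778	809
6a	AAANTYAAANRAATWGRCGGGGRCCCGCACAAG	906	938
6b	ATGTGGTTTAATTCGA	948	963
6c	CAACGCGARGAACCTTACC	966	984
7a	AGGTGNTGCATGGYYGYCGTCAGCTCGTGYCGTGAG	1045	1080
7b	TGTTGGGTTAAGTCCCRYAACGAGCGCAACCCT	1082	1114
8a	GGAAGGYGGGGAYGACG	1176	1192
8b	GGGCKACACACGYGCTAC	1219	1236
9	GCCTTGYACWCWCCGCCCGTC	1386	1406
10	GGGTGAAGTCRTAACAAGGTANCC	1486	1509
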