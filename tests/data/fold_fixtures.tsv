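# id	seq	dotbracket	mfe (recorded from the bundled thermo backend)
clean_hairpin	GTGCTAGACTCAGGGCATCGCGAATGGCGAGATTCGCGATGCCCTGAGTCTAGCAC	(((((((((((((((((((((((((......)))))))))))))))))))))))))	-33.387538
bulged_hairpin	ATAAGGAAAAGCGGGGAAGAGGCCATAGCAGTCCCTGCTATGGCCTCTTCCCCGCTATCTTCCTTAT	((((((((.((((((((((((((((((((((...))))))))))))))))))))))...))))))))	-35.906853
low_gc_hairpin	GTATGCTAGTAGGTTTTAACCTTTTAATAATGTGACAAAAGGTTAAAACGCTAACTAGCATAC	((((((((((..(((((((((((((...........)))))))))))))....))))))))))	-16.422176
random_80	GCTAAAGACAATTACATAACATACACGTCAGCACGAAACTTGTTGGCCCAGTGTGAATCGCTTAAGGGTTAAGTAAGTGT	.....................((((((((((((.......)))))))...)))))....((((((...))))))......	-2.519360
random_120	GATGCATACGCCTTTACTTGCTGTGTCCACCCCATCGGACTGGCATTTTTATTACACTCAGAAACAGAACTCGGGTAATTTTGACAGGTCACGCAGAGGCGCGCCCTCCTGAAGTGCGTG	..................(((((.((((........)))))))))............................................((((((((((.....))))......))))))	-5.117420
unpaired	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	..............................	0.000000
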