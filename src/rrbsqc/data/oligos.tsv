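# Oligonucleotides of the two-step methylated-adaptor RRBS protocol, as
# annotated: **C** marks 5-methylcytosine, lowercase s a phosphorothioate
# bond, p- a 5' phosphate, -OH the 3' hydroxyl, and *NNNNNN* the 6-nt index
# of an indexing primer.  Lengths and indices are computed after stripping
# the annotation characters.
name	sequence
mC-PE1	A**C**A**C**T**C**TTT**CCC**TA**C**A**C**GA**C**G**C**T**C**TT**CC**GAT**C**sT-OH
mC-PE2	p-GAT**C**GGAAGAG**C**GGTT**C**AG**C**AGGAATG**CC**GAG-OH
IndPEPCR_F	AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCsT
IndPEPCR_R	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCsT
PE-qPCR_F	AATGATACGGCGACCACCGA-OH
PE-qPCR_R	CAAGCAGAAGACGGCATACGA-OH
Index_1R	CAAGCAGAAGACGGCATACGAGAT*CGTGAT*GTGACTGGAGTTC-OH
Index_2R	CAAGCAGAAGACGGCATACGAGAT*ACATCG*GTGACTGGAGTTC-OH
Index_3R	CAAGCAGAAGACGGCATACGAGAT*GCCTAA*GTGACTGGAGTTC-OH
Index_4R	CAAGCAGAAGACGGCATACGAGAT*TGGTCA*GTGACTGGAGTTC-OH
Index_5R	CAAGCAGAAGACGGCATACGAGAT*CACTGT*GTGACTGGAGTTC-OH
Index_6R	CAAGCAGAAGACGGCATACGAGAT*ATTGGC*GTGACTGGAGTTC-OH
Index_7R	CAAGCAGAAGACGGCATACGAGAT*GATCTG*GTGACTGGAGTTC-OH
Index_8R	CAAGCAGAAGACGGCATACGAGAT*TCAAGT*GTGACTGGAGTTC-OH
Index_9R	CAAGCAGAAGACGGCATACGAGAT*CTGATC*GTGACTGGAGTTC-OH
Index_10R	CAAGCAGAAGACGGCATACGAGAT*AAGCTA*GTGACTGGAGTTC-OH
Index_11R	CAAGCAGAAGACGGCATACGAGAT*GTAGCC*GTGACTGGAGTTC-OH
Index_12R	CAAGCAGAAGACGGCATACGAGAT*GAACAT*GTGACTGGAGTTC-OH
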