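# Reference methylation expectations for control CpG islands in adult human
# brain RRBS data (hg19 coordinates, 0-based half-open).  Imprinted islands
# (polarity imprinted_mid) carry parent-of-origin monoallelic methylation and
# are expected near their characteristic mid-range level; GAPDH and ACTB are
# unmethylated housekeeping islands (polarity unmethylated_low).  Expectations
# are tissue-specific: supply your own table for non-brain samples.
# pct_* columns are published per-subject methylation percentages from four
# adult brain samples; expected_mean_pct/expected_sd_pct are the published
# across-subject mean +/- SD used in pass/fail checks.  The sperm_pct column
# is annotation from an independent tissue and is never used in checks.
gene	contig	start	end	pct_B02	pct_D07	pct_E08	pct_G12	expected_mean_pct	expected_sd_pct	polarity	sperm_pct
IGF2R	chr6	160426264	160427502	46.4	50.0	57.4	49.4	50.8	4.7	imprinted_mid	69.8
GRB10	chr7	50849752	50850871	24.8	28.5	27.2	24.5	26.3	1.9	imprinted_mid	45.2
PEG3	chr19	57351283	57351995	38.0	44.7	34.1	30.1	36.7	6.3	imprinted_mid	42.0
MEST	chr7	130130739	130133111	34.4	33.9	37.2	34.3	35.0	1.5	imprinted_mid	49.9
RB1	chr13	48892635	48893857	60.9	61.2	56.4	60.1	59.7	2.2	imprinted_mid	57.7
KCNQ1	chr11	2720410	2722087	39.2	36.9	36.4	36.9	37.4	1.3	imprinted_mid	50.4
GAPDH	chr12	6643261	6644607	1.4	0.7	1.8	1.3	1.3	0.5	unmethylated_low
ACTB	chr7	5569062	5570594	0.8	0.4	1.7	1.0	1.0	0.5	unmethylated_low
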