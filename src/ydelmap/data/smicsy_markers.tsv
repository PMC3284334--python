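# Published Y-chromosome-specific STS markers from the compound-SSR screen (SmicSy1-6).
# specific_primer is the forward primer; ssr_partner names the compound SSR reverse primer.
# annealing_temp_C is wet-lab gradient-PCR metadata, unused by the in-silico binding model.
name	specific_primer	ssr_partner	annealing_temp_C
SmicSy1	CTCACCGTAGCCGAGAAGAAGGAGAAAGG	SSR-5_27M	60
SmicSy2	TGTCGATCGTTCAAAGCAACTACAGG	SSR-5_27M	60
SmicSy3	GCTCCCAACACTACGCCTTA	SSR-5_27M	63
SmicSy4	GCAAATGAAATCATCTCGACTG	SSR-4_27M	63
SmicSy5	AGTCGAGAGGCACGAAAATG	SSR-4_27M	58
SmicSy6	CCATTTCAATTTGGGGTTTG	SSR-4_27M	60
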