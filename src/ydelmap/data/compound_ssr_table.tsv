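# Compound SSR primer formulas: five two-unit combinations x four arrangement patterns.
# Simple arrangements (21S/27S) are pure tandem repeats; modified arrangements (21M/27M)
# carry partial-unit flanks at the 5' and 3' ends, transcribed per combination as published.
# Formula syntax: optional 5' flank, (UNIT)n blocks, optional 3' flank.
combination	unit_a	unit_b	arrangement	formula
SSR-1	CAG	CAA	21S	(CAG)4(CAA)3
SSR-1	CAG	CAA	21M	AG(CAG)3(CAA)3C
SSR-1	CAG	CAA	27S	(CAG)5(CAA)4
SSR-1	CAG	CAA	27M	AG(CAG)6(CAA)2C
SSR-2	CAG	CAT	21S	(CAG)4(CAT)3
SSR-2	CAG	CAT	21M	AG(CAG)3(CAT)3C
SSR-2	CAG	CAT	27S	(CAG)5(CAT)4
SSR-2	CAG	CAT	27M	AG(CAG)6(CAT)2C
SSR-3	CAG	GAA	21S	(CAG)4(GAA)3
SSR-3	CAG	GAA	21M	AG(CAG)3(GAA)3G
SSR-3	CAG	GAA	27S	(CAG)5(GAA)4
SSR-3	CAG	GAA	27M	AG(CAG)6(GAA)2G
SSR-4	CAA	GAA	21S	(CAA)4(GAA)3
SSR-4	CAA	GAA	21M	AA(CAA)3(GAA)3G
SSR-4	CAA	GAA	27S	(CAA)5(GAA)4
SSR-4	CAA	GAA	27M	AA(CAA)6(GAA)2G
SSR-5	CAA	TAA	21S	(CAA)4(TAA)3
SSR-5	CAA	TAA	21M	AA(CAA)3(TAA)3T
SSR-5	CAA	TAA	27S	(CAA)5(TAA)4
SSR-5	CAA	TAA	27M	AA(CAA)6(TAA)2T
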