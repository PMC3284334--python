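# SYNTHETIC stand-in for the published 19-mutant x 25-marker Y deletion panel.
# The published matrix is a figure; this reconstruction enforces every row fact stated in
# the accompanying text: GP1 has 24/25 markers deleted, GP2 has 20, LSS1 loses only
# SmicSy3+SmicSy4, GP9 loses only SmicSy1/2/5/6, exactly five mutants (ISS1, ISS2, ISS5,
# GP7, R025) carry no detectable Y deletion, the ESS mutants lose ScQ14 and SmicSy1/5/6,
# SmicSy5 and SmicSy6 share a deletion pattern with SmicSy6 placed nearer ScQ14, and the
# hermaphrodite deletions cluster around MK17 (the GSF-proximal marker). Columns are in
# map order. Marker names other than MK17, ScQ14 and SmicSy1-6, the mutant names GP5/GP6,
# and the K034 row are constructions. Cells: 1 present, 0 deleted, R present but
# reduced-size fragment.
mutant	phenotype	MK17	ORF01	ORF02	STS01	STS02	ORF03	STS03	ScQ14	SmicSy6	SmicSy5	SmicSy1	SmicSy2	ORF04	STS04	ORF05	SmicSy3	SmicSy4	ORF06	STS05	ORF07	ORF08	STS06	ORF09	ORF10	ORF11
GP1	hermaphrodite_incomplete	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1
GP2	hermaphrodite_incomplete	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	R	1	1	1	1
GP3	hermaphrodite_incomplete	0	0	0	0	0	R	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
GP4	hermaphrodite_complete	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
GP5	hermaphrodite_complete	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
GP6	hermaphrodite_incomplete	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
GP7	hermaphrodite_incomplete	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
GP9	hermaphrodite_incomplete	1	1	1	1	1	1	1	1	0	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1
ESS1	ESS	1	1	1	1	1	1	1	0	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1
ESS2	ESS	1	1	1	1	1	1	0	0	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1
ESS3	ESS	1	1	1	1	1	0	0	0	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1
ISS1	ISS	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
ISS2	ISS	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
ISS3	ISS	1	1	1	1	1	1	1	1	1	1	1	1	0	0	1	1	1	1	1	1	1	1	1	1	1
ISS4	ISS	1	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	1	1	1
ISS5	ISS	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
LSS1	LSS	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	R	1	1	1	1	1	1	1
K034	hermaphrodite_complete	0	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
R025	hermaphrodite_complete	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
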