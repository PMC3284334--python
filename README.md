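# ydelmap

In-silico compound-microsatellite marker discovery and deletion-panel mapping
of plant sex-determination regions.

## The problem

Dioecious plants with XY sex chromosomes (the white campion is the classic
model) carry three maleness factors on the Y: a gynoecium-suppressing factor
(GSF), a stamen-promoting factor (SPF) and a male-fertility factor (MFF).
Deleting them produces, respectively, hermaphrodite, early-stamen-suppressed
(ESS) and late-stamen-suppressed (LSS) flowers.  Because the Y is huge,
non-recombining and repeat-rich, the factors are mapped ordinally: panels of
irradiation-induced Y-deletion mutants are genotyped with Y-specific
sequence-tagged-site (STS) markers, and a factor is pinned to the interval
jointly deleted by its phenotype class.

The marker-discovery trick exploited here is the *compound* microsatellite: a
primer spanning the switch point of two tandemly arrayed trinucleotide
repeats, e.g. `(CAG)4(CAA)3`, is locally unique even inside repeat-dense
sequence.  Twenty such primers (five unit combinations x four arrangement
patterns: 21/27-mer, simple/modified flanks) are paired with an adaptor
primer over a suppression-PCR library of restriction-digested male DNA;
flank-specific primers from the amplified fragments are then screened on male
versus female templates, and male-only markers (named `SmicSy`) are
Y-chromosome specific.

`ydelmap` implements the whole workflow on synthetic dioecious genomes: the
genome and mutant-panel simulator, the 20-primer set and oligo constants, the
restriction/ligation/suppression-PCR model, the specificity screen, and the
deletion-panel mapping inference.  It is a package for method exploration and
teaching, not a wet-lab replacement.

## The core inference

Given the binary mutant x marker matrix `C` (1 = fragment amplified), choose
a marker permutation π minimizing the total number of deletion blocks

&nbsp;&nbsp;&nbsp;&nbsp;`B(π) = Σ_mutants #{maximal runs of 0s in row under π}`,

the formal reading of "order markers to minimize deletion sites".  If every
mutant carries one contiguous deletion, the true order attains one block per
deleted mutant (the consecutive-ones property).  Small panels are solved
exactly by branch-and-bound over permutations (canonicalized against
reversal); large ones by greedy co-deletion adjacency construction plus 2-opt
refinement with seeded restarts.  A factor is localized to the intersection
of its phenotype class's deleted spans, flanked by the nearest markers
retained by every mutant of the class.

## Worked example

```python
import ydelmap as y

panel = y.load_synthetic_panel()          # 19 mutants x 25 markers
res = y.DeletionMapping(panel).fit(method="heuristic", seed=0)
print(res.summary())
```

prints (abridged):

```
markers: 25   mutants: 19 (14 with deletions)
solver: heuristic (greedy + 2-opt)
objective (blocks): 14
orientation: arbitrary up to reversal

order: MK17 - ORF01 - ORF02 - STS01 - STS02 - ORF03 - STS03 - ScQ14 -
       SmicSy1 - SmicSy5 - SmicSy6 - SmicSy2 - ORF04 - ... - ORF11

  SPF [ESS]: STS02 < [ScQ14, SmicSy1, SmicSy5, SmicSy6] < SmicSy2
  MFF [LSS]: STS05 < [SmicSy3, SmicSy4] < ORF08
```

The objective of 14 equals the number of mutants carrying deletions — every
mutant's loss is explained by a single contiguous block, so the panel is
perfectly consistent with contiguous Y deletions.  SPF falls in the
ScQ14/SmicSy6-proximal interval jointly deleted by the ESS class, and MFF in
the SmicSy3–SmicSy4 interval lost by the LSS mutant.  `res.localize("hermaphrodite_complete")`
pins GSF to MK17 and reports R025 (deletion-free) as unexplained.

The full simulation loop is one command:

```sh
ydelmap run-all --seed 42 --outdir out/
```

which simulates a male/female genome pair, builds the three enzyme libraries,
amplifies with all 20 compound-SSR primers, designs and screens specific
primers, genotypes a simulated mutant panel with the male-specific markers,
and writes the inferred marker order and factor intervals.

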