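# Methods

## Scope and model

`ydelmap` reproduces, as executable models, the computational skeleton of
compound-SSR Y-marker discovery and deletion mapping in a dioecious XY plant:

1. a synthetic genome generator emulating the microsatellite landscape the
   screen relies on;
2. the 20-primer compound-SSR set and the suppression-PCR library model;
3. an informatic primer-binding and male/female specificity screen;
4. deletion-panel genotyping, marker ordering by deletion-site minimization,
   and factor localization.

Coordinates are 0-based half-open everywhere.  All stochastic steps draw from
a single seeded `numpy` generator per call, sampled in a fixed documented
order, so every artifact is reproducible from (config, seed).

## Synthetic genomes

Background sequence is i.i.d. with configurable GC (default 0.42, mildly
AT-rich as is typical for plant nuclear DNA).  Trinucleotide tracts are
placed by a Poisson process with per-chromosome, per-unit rates; defaults
encode the cytogenetic picture motivating the screen: CAA tracts at
5/10 kb on the Y versus 1/10 kb on X and autosomes, GAA/TAA mildly
Y-enriched, CAG/CAT equal everywhere.  A configurable fraction of tracts
(default 0.35) is compound — a second unit drawn from the five screened
combinations appended in tandem — because the compound-primer design targets
exactly these switch points.  Tract copy numbers are 2 plus a geometric
excess (mean 4 for the first unit, 1.5 for the second): short tracts
dominate, matching the observation that genomic microsatellites are mostly
short.  After placement the flanking bases are adjusted so each annotated
run is maximal; annotations are therefore recoverable exactly by an
independent maximal-run scanner, which the test suite asserts.

Three factor loci (GSF, SPF, MFF) sit at fixed fractional positions of the Y
(defaults 0.10–0.12, 0.45–0.47, 0.75–0.77).  An optional fourth locus M2
adjacent to SPF models the intermediate (ISS) stamen class; it is off by
default because the three-factor model is the core, and ISS mutants can also
be simulated with no Y deletion at all (a configurable fraction of panel
mutants, default 5/19, carries no deletion — several real mutant classes
show phenotypes without detectable Y marker loss).

Deletion sizes are gamma-distributed (default mean 10 kb, shape 2), a
right-skewed family that supports both sub-kilobase hits and multi-locus
sweeps; the published panels report marker counts, not physical sizes, so
the distribution is a package choice, not a measured one.  Phenotypes follow
factor overlap: GSF→hermaphrodite, SPF→ESS, M2→ISS, MFF→LSS, none→WT_male;
multi-factor hits get a composite `+`-joined label rather than a silently
chosen single class.

The matched female genome reuses the male's autosomes and X (one copy
standing for the homozygous pair), modeling an inbred line; male-specificity
then reduces exactly to Y-linkage.

## Library and PCR model

Digestion uses the three blunt cutters EcoRV (`GAT^ATC`), DraI (`TTT^AAA`)
and SspI (`AAT^ATT`) via Biopython's restriction catalogue; fragments always
partition the input.  Blunt-adaptor ligation flags both fragment ends; the
capped adaptor strand is modeled as a *rule*, not a molecule: no product can
initiate from the adaptor alone, so amplification requires a
fragment-internal compound-SSR primer site (suppression PCR).  Products run
from the SSR primer through the fragment end and 35 nt into the adaptor (up
to and including the reverse complement of AP2).

Primer binding is informatic, not thermodynamic: a site requires an exact
match over the 3'-terminal `seed_len` bases (default 10) and at most
`max_mismatch` (default 2) mismatches elsewhere, on either strand.  Products
are accepted between 50 and 3000 nt.  The defaults are permissive enough to
reproduce shared (autosomal/X) bands yet strict enough that a unique
20-mer flank discriminates the Y; all are exposed in `BindingParams`.
Annealing temperatures in the marker table are wet-lab metadata and are
never consulted.  There is no repeat-slippage model: compound primers bind
genomic tracts under the same mismatch rule as any primer.

Specific primers are designed deterministically from the amplicon interior
(leftmost window ≥ 20 nt past the SSR end, lengths 18–30 trying 20 first,
GC 30–70%, no internal trinucleotide tandem): the primer is the reverse
complement of the window so it points back toward the compound-SSR site and
the (specific, SSR-partner) pair defines a product.  Gel comparison treats
product lengths within ±5% as one band (agarose-like resolution): male-only
bands are `SmicSy_male_specific`, 1–2 bands in both sexes `SmicS_shared`,
more than two bands `nonspecific` (discarded, mirroring smeary patterns),
otherwise `no_product`.

## Ordering and localization

The mapping objective is the total number of deletion blocks — maximal runs
of absent calls per mutant, summed — the formalization of "minimize deletion
sites".  Reduced-size cells (fragment present but shorter, i.e. a deletion
interior to the amplicon sparing both primer sites) count as present for
ordering, with the annotation preserved.  Mutants with no deletions
contribute zero under every order and are excluded from the search.  An
alternative objective (total adjacent call changes, "breakpoints") is
available but off by default.

The exact solver is a two-pass branch-and-bound: pass one establishes the
optimum (lower bound: closed runs + rows with an open or pending run; upper
bound seeded by the heuristic), pass two re-walks the tree in sorted-name
order and returns the first permutation attaining it, which is the
lexicographically smallest global minimizer and hence reversal-canonical.
It refuses panels above 10 markers.  The heuristic builds a path greedily on
co-deletion similarity, refines it by best-improvement 2-opt using O(1)
objective evaluation from precomputed transition tables, and takes the best
of 10 seeded restarts; it is deterministic given (panel, seed) and its
objective is bounded below by the exact optimum.

Factor localization intersects the deleted marker sets of a phenotype
class's mutants under a given order; flanks are the nearest markers retained
by every supporting mutant.  Class members without deletions are reported as
unexplained rather than dropped silently; an empty intersection raises an
error naming the incompatible mutants, since it suggests more than one
underlying locus.  Two caveats are inherent to the objective: (i) map
orientation is unidentifiable, so results carry an explicit
"arbitrary up to reversal" flag; (ii) markers deleted in *no* mutant are
unconstrained and may be placed anywhere at zero cost, so flank identity is
only meaningful given a fixed (true or externally anchored) order — the
recovery tests therefore assert interval containment under the known order,
and order recovery itself only where every adjacent marker pair is separated
by at least one deletion breakpoint.

## Packaged data

Three small TSVs ship with the package: the compound-SSR formula table
(five combinations x four arrangements, with the modified-arrangement flanks
transcribed per combination because no single rule generates them), the six
published `SmicSy` marker records, and a 19-mutant x 25-marker deletion
panel.  The panel is a *constructed stand-in* (`deletion_panel_synthetic.tsv`):
the published matrix exists only as a figure, so the file enforces every row
fact stated in the accompanying text (GP1 24/25 deleted, GP2 20, LSS1 only
SmicSy3+4, GP9 only SmicSy1/2/5/6, exactly five deletion-free mutants, the
ESS deletion pattern, the SmicSy5/6 pattern identity) and invents the rest;
its header says so.

## What the simulations do and do not show

Passing tests demonstrate internal correctness and consistency: digestion
partitions, binding-scan equivalence with brute force, exact-solver
agreement with exhaustive search, screen soundness (no Y-specific call ever
amplifies on the XX genome), and ground-truth recovery on noiseless panels.
They do not show field performance on real genomes: real microsatellite
landscapes are non-Poisson and autocorrelated, X/Y homology is modeled only
through shared ancestry of the X (not degenerate gametologs), PCR competition
and annealing-temperature effects are absent, and genotyping is noiseless
where real panels need replicate PCRs.  Yields in the demo screen are
therefore far higher than the published 1% — the synthetic Y is small and
CAA-dense, and every candidate primer is tested without cloning losses.

## Problem sizes

Default test and demo sizes (60–200 kb chromosomes, 12–19 mutants, 20–25
markers, 100-panel recovery sweeps) were chosen so a full suite run and an
acceptance-script run each complete in well under a minute of CPU while
keeping Poisson counts and recovery rates statistically stable; all sizes
are configuration, not code.
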