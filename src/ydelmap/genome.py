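"""Synthetic dioecious genomes with Y-enriched trinucleotide microsatellites.

The generator emulates the genomic structure the compound-SSR marker screen
relies on: an XY male genome whose Y chromosome is enriched for CAA-containing
trinucleotide tracts relative to X and the autosomes (as cytogenetic
hybridization of such probes indicates for the target system), with some
tracts compound (two different units in tandem) and all tracts embedded in
unique single-copy flanking sequence.  The Y additionally carries three
ordered sex-determination factor loci — GSF (gynoecium-suppressing factor),
SPF (stamen-promoting factor) and MFF (male-fertility factor) — whose
deletion produces hermaphrodite, early-stamen-suppressed (ESS) and
late-stamen-suppressed (LSS) phenotypes respectively.  An optional second
late-acting locus M2 adjacent to SPF models intermediate (ISS) mutants.

Coordinates are 0-based half-open throughout.  Background sequence is i.i.d.
with configurable GC; all randomness flows from a single seeded generator per
simulation call, sampled in a fixed documented order (chromosomes in a fixed
order; within a chromosome: background, then tracts unit-by-unit in sorted
unit order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

AUTOSOME = "autosome"
X = "X"
Y = "Y"

FACTOR_ORDER = ("GSF", "SPF", "MFF")
FACTOR_PHENOTYPE = {"GSF": "hermaphrodite", "SPF": "ESS", "M2": "ISS", "MFF": "LSS"}
WT_MALE = "WT_male"

# Second units available to a compound tract, by first unit (the five screened
# combinations: CAG+CAA, CAG+CAT, CAG+GAA, CAA+GAA, CAA+TAA).
COMPOUND_PARTNERS = {"CAG": ("CAA", "CAT", "GAA"), "CAA": ("GAA", "TAA")}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SSRTract:
    """One annotated microsatellite tract (compound = two units in tandem)."""

    chrom: str
    start: int
    unit: str
    copies: int
    is_compound: bool = False
    second_unit: str | None = None
    second_copies: int = 0

    @property
    def end(self) -> int:
        n = 3 * self.copies
        if self.is_compound:
            n += 3 * self.second_copies
        return self.start + n

    @property
    def sequence(self) -> str:
        s = self.unit * self.copies
        if self.is_compound:
            s += self.second_unit * self.second_copies
        return s


@dataclass
class GenomeModel:
    chromosomes: dict[str, str]
    sex_linkage: dict[str, str]
    ssr_tracts: list[SSRTract] = field(default_factory=list)
    factor_loci: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def is_male(self) -> bool:
        return Y in self.sex_linkage.values()

    def _single(self, linkage: str) -> str:
        names = [c for c, l in self.sex_linkage.items() if l == linkage]
        if len(names) != 1:
            raise ValueError(f"genome has {len(names)} {linkage} chromosomes")
        return names[0]

    @property
    def y_name(self) -> str:
        return self._single(Y)

    @property
    def x_name(self) -> str:
        return self._single(X)

    def validate(self) -> None:
        if set(self.chromosomes) != set(self.sex_linkage):
            raise ValueError("chromosomes and sex_linkage disagree")
        linkages = list(self.sex_linkage.values())
        if self.is_male:
            if linkages.count(Y) != 1 or linkages.count(X) != 1:
                raise ValueError("male genome must carry exactly one X and one Y")
        elif linkages.count(X) != 1:
            raise ValueError("female genome must carry exactly one X and no Y")
        if self.factor_loci:
            y = self.chromosomes[self.y_name]
            ivals = sorted(self.factor_loci.values())
            for (s, e) in ivals:
                if not (0 <= s < e <= len(y)):
                    raise ValueError("factor locus outside Y bounds")
            for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError("factor loci overlap")
        for t in self.ssr_tracts:
            seq = self.chromosomes[t.chrom]
            if seq[t.start : t.end] != t.sequence:
                raise ValueError(f"tract at {t.chrom}:{t.start} mismatches sequence")


@dataclass
class MutantGenome:
    """A deletion derivative of a base genome.

    ``deletions`` maps chromosome -> disjoint sorted half-open intervals on the
    *base* coordinate system.  ``phenotype`` is the factor-overlap class (see
    :func:`classify_phenotype`); composite classes join single-factor labels
    with ``+``.
    """

    name: str
    base: GenomeModel
    deletions: dict[str, list[tuple[int, int]]]
    phenotype: str | None = None

    def __post_init__(self) -> None:
        for chrom, ivals in self.deletions.items():
            if chrom not in self.base.chromosomes:
                raise ValueError(f"{self.name}: unknown chromosome {chrom}")
            L = len(self.base.chromosomes[chrom])
            prev_end = 0
            for s, e in sorted(ivals):
                if not (0 <= s < e <= L):
                    raise ValueError(f"{self.name}: deletion {chrom}:{s}-{e} out of bounds")
                if s < prev_end:
                    raise ValueError(f"{self.name}: overlapping deletions on {chrom}")
                prev_end = e
            self.deletions[chrom] = sorted(ivals)

    def chromosome_sequence(self, chrom: str) -> str:
        seq = self.base.chromosomes[chrom]
        ivals = self.deletions.get(chrom)
        if not ivals:
            return seq
        parts, pos = [], 0
        for s, e in ivals:
            parts.append(seq[pos:s])
            pos = e
        parts.append(seq[pos:])
        return "".join(parts)

    @property
    def y_deletions(self) -> list[tuple[int, int]]:
        return self.deletions.get(self.base.y_name, [])

    def deleted_length(self, chrom: str) -> int:
        return sum(e - s for s, e in self.deletions.get(chrom, []))


@dataclass
class GenomeConfig:
    """Study conditions for the synthetic genome.

    Tract rates are expected tract counts per 10 kb, by sex linkage and repeat
    unit; the defaults encode Y enrichment of CAA (and, more weakly, GAA/TAA)
    with CAG at roughly equal density on all chromosomes.
    """

    autosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 60_000, "chr2": 60_000}
    )
    x_length: int = 120_000
    y_length: int = 200_000
    gc: float = 0.42
    tract_rates_per_10kb: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            AUTOSOME: {"CAA": 1.0, "CAG": 1.0, "CAT": 0.5, "GAA": 0.4, "TAA": 0.4},
            X: {"CAA": 1.0, "CAG": 1.0, "CAT": 0.5, "GAA": 0.4, "TAA": 0.4},
            Y: {"CAA": 5.0, "CAG": 1.0, "CAT": 0.5, "GAA": 1.2, "TAA": 1.2},
        }
    )
    compound_fraction: float = 0.35
    mean_extra_copies: float = 4.0
    mean_extra_second_copies: float = 1.5
    min_gap: int = 30
    factor_fractions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "GSF": (0.10, 0.12),
            "SPF": (0.45, 0.47),
            "MFF": (0.75, 0.77),
        }
    )
    include_m2: bool = False
    m2_fraction: tuple[float, float] = (0.475, 0.495)


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _break_unit(seq: np.ndarray, pos: int, unit: str) -> None:
    """Ensure seq[pos] differs from unit[k] so no extra full unit copy abuts."""
    current = chr(seq[pos])
    if current == unit[-1] or current == unit[0]:
        for b in "TGCA":
            if b not in (unit[0], unit[-1]):
                seq[pos] = ord(b)
                break


def _place_tracts(
    rng: np.random.Generator,
    seq: np.ndarray,
    chrom: str,
    rates: dict[str, float],
    cfg: GenomeConfig,
) -> list[SSRTract]:
    L = len(seq)
    p_extra = 1.0 / (1.0 + cfg.mean_extra_copies)
    p_extra2 = 1.0 / (1.0 + cfg.mean_extra_second_copies)
    occupied: list[tuple[int, int]] = []
    tracts: list[SSRTract] = []
    for unit in sorted(rates):
        rate = rates[unit]
        if rate < 0:
            raise ValueError("tract rates must be >= 0")
        n = rng.poisson(rate * L / 10_000.0) if rate > 0 else 0
        for _ in range(n):
            copies = 2 + int(rng.geometric(p_extra)) - 1
            is_compound = bool(rng.random() < cfg.compound_fraction)
            second_unit, second_copies = None, 0
            if is_compound:
                partners = COMPOUND_PARTNERS.get(
                    unit, tuple(u for u in sorted(rates) if u != unit) or ("GAA",)
                )
                second_unit = partners[int(rng.integers(len(partners)))]
                second_copies = 2 + int(rng.geometric(p_extra2)) - 1
            tlen = 3 * copies + (3 * second_copies if is_compound else 0)
            if tlen + 2 * cfg.min_gap >= L:
                raise ValueError(
                    f"{chrom}: tract of {tlen} nt cannot fit in {L} nt chromosome"
                )
            placed = False
            for _attempt in range(200):
                start = int(rng.integers(cfg.min_gap, L - tlen - cfg.min_gap))
                end = start + tlen
                if all(
                    end + cfg.min_gap <= s or e + cfg.min_gap <= start
                    for s, e in occupied
                ):
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"{chrom}: SSR density too high, tracts overlap irreducibly"
                )
            tract = SSRTract(
                chrom=chrom,
                start=start,
                unit=unit,
                copies=copies,
                is_compound=is_compound,
                second_unit=second_unit,
                second_copies=second_copies,
            )
            body = np.frombuffer(tract.sequence.encode(), dtype=np.uint8)
            seq[start:end] = body
            # keep the annotated run maximal: no full extra unit copy on either side
            if seq[start - 3 : start].tobytes().decode() == unit:
                _break_unit(seq, start - 1, unit)
            last_unit = second_unit if is_compound else unit
            if seq[end : end + 3].tobytes().decode() == last_unit:
                _break_unit(seq, end, last_unit)
            occupied.append((start, end))
            tracts.append(tract)
    tracts.sort(key=lambda t: t.start)
    return tracts


def simulate_genome(
    config: GenomeConfig | None = None, seed: int = 0, sex: str = "male"
) -> GenomeModel:
    """Simulate a male (XY) or female (XX, represented by one X copy) genome.

    Reproducible: one seeded generator drives all sampling in a fixed order.
    Raises ``ValueError`` for non-positive chromosome lengths or SSR densities
    so high that tract placement fails.
    """
    cfg = config or GenomeConfig()
    lengths = dict(sorted(cfg.autosome_lengths.items()))
    linkage = {c: AUTOSOME for c in lengths}
    lengths["chrX"] = cfg.x_length
    linkage["chrX"] = X
    if sex == "male":
        lengths["chrY"] = cfg.y_length
        linkage["chrY"] = Y
    elif sex != "female":
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if any(L <= 0 for L in lengths.values()):
        raise ValueError("chromosome lengths must be positive")

    rng = np.random.default_rng(seed)
    chromosomes: dict[str, str] = {}
    tracts: list[SSRTract] = []
    for chrom in lengths:  # insertion order: sorted autosomes, chrX, chrY
        seq = _random_background(rng, lengths[chrom], cfg.gc)
        rates = cfg.tract_rates_per_10kb.get(linkage[chrom], {})
        tracts.extend(_place_tracts(rng, seq, chrom, rates, cfg))
        chromosomes[chrom] = seq.tobytes().decode()

    factor_loci: dict[str, tuple[int, int]] = {}
    if sex == "male":
        Ly = cfg.y_length
        fractions = dict(cfg.factor_fractions)
        if cfg.include_m2:
            fractions["M2"] = cfg.m2_fraction
        for name, (a, b) in fractions.items():
            factor_loci[name] = (int(a * Ly), int(b * Ly))

    genome = GenomeModel(
        chromosomes=chromosomes,
        sex_linkage=linkage,
        ssr_tracts=tracts,
        factor_loci=factor_loci,
    )
    genome.validate()
    return genome


def female_from_male(male: GenomeModel) -> GenomeModel:
    """The matched XX genome of the same inbred line: identical autosomes and X,
    no Y (one X copy represents the homozygous pair)."""
    y = male.y_name
    return GenomeModel(
        chromosomes={c: s for c, s in male.chromosomes.items() if c != y},
        sex_linkage={c: l for c, l in male.sex_linkage.items() if c != y},
        ssr_tracts=[t for t in male.ssr_tracts if t.chrom != y],
        factor_loci={},
    )


def _overlaps(ivals: Sequence[tuple[int, int]], locus: tuple[int, int]) -> bool:
    s2, e2 = locus
    return any(s1 < e2 and s2 < e1 for s1, e1 in ivals)


def classify_phenotype(mutant: MutantGenome) -> str:
    """Phenotype class from factor-locus overlap with Y deletions.

    GSF hit -> hermaphrodite; SPF hit -> ESS; M2 hit (when annotated) -> ISS;
    MFF hit -> LSS; no hit -> WT_male.  Multi-factor deletions yield a
    composite ``+``-joined label (e.g. ``hermaphrodite+ESS+LSS``) rather than
    silently collapsing to one class.
    """
    loci = mutant.base.factor_loci
    missing = [f for f in FACTOR_ORDER if f not in loci]
    if missing:
        raise ValueError(f"base genome lacks factor annotation: {missing}")
    dels = mutant.y_deletions
    order = [f for f in ("GSF", "SPF", "M2", "MFF") if f in loci]
    hits = [FACTOR_PHENOTYPE[f] for f in order if _overlaps(dels, loci[f])]
    if not hits:
        return WT_MALE
    return "+".join(hits)


@dataclass
class DeletionSizeDist:
    """Gamma-distributed deletion sizes (nt); supports sub-kb through
    multi-locus deletions depending on ``mean``."""

    mean: float = 10_000.0
    shape: float = 2.0

    def sample(self, rng: np.random.Generator) -> int:
        return max(1, int(round(rng.gamma(self.shape, self.mean / self.shape))))


def simulate_deletion_panel(
    genome: GenomeModel,
    n_mutants: int,
    size_dist: DeletionSizeDist | None = None,
    seed: int = 0,
    no_deletion_fraction: float = 5 / 19,
    deletions_per_mutant: int = 1,
    name_prefix: str = "mut",
) -> list[MutantGenome]:
    """Simulate a panel of Y-deletion mutants of ``genome``.

    Each mutant carries ``deletions_per_mutant`` contiguous Y deletions with
    gamma-distributed sizes, except a configurable fraction that carries none
    (mutant phenotypes can arise without a detectable Y deletion).  Phenotypes
    are assigned by :func:`classify_phenotype`.
    """
    if n_mutants < 0:
        raise ValueError("n_mutants must be >= 0")
    dist = size_dist or DeletionSizeDist()
    y = genome.y_name
    Ly = len(genome.chromosomes[y])
    rng = np.random.default_rng(seed)
    mutants: list[MutantGenome] = []
    for i in range(n_mutants):
        ivals: list[tuple[int, int]] = []
        if rng.random() >= no_deletion_fraction:
            for _ in range(deletions_per_mutant):
                for _attempt in range(200):
                    size = dist.sample(rng)
                    if size > Ly:
                        raise ValueError(
                            f"sampled deletion of {size} nt exceeds Y length {Ly}"
                        )
                    start = int(rng.integers(0, Ly - size + 1))
                    iv = (start, start + size)
                    if not _overlaps(ivals, iv):
                        ivals.append(iv)
                        break
                else:
                    raise ValueError("could not place disjoint deletions")
        mut = MutantGenome(
            name=f"{name_prefix}{i + 1:03d}",
            base=genome,
            deletions={y: sorted(ivals)} if ivals else {},
        )
        mut.phenotype = classify_phenotype(mut)
        mutants.append(mut)
    return mutants


# --------------------------------------------------------------------------
# File formats: multi-FASTA genomes, BED tracts/factors/deletions, TSV manifest
# --------------------------------------------------------------------------


def write_genome_fasta(genome: GenomeModel, path: str | Path) -> None:
    """Multi-FASTA with the sex linkage recorded in each header description."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=chrom, description=genome.sex_linkage[chrom])
        for chrom, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> GenomeModel:
    from Bio import SeqIO

    chromosomes, linkage = {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        chromosomes[rec.id] = str(rec.seq)
        parts = rec.description.split()
        linkage[rec.id] = parts[1] if len(parts) > 1 else AUTOSOME
    return GenomeModel(chromosomes=chromosomes, sex_linkage=linkage)


def write_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """(chrom, start, end, name) rows, 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, s, e, name in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def tracts_bed_rows(genome: GenomeModel) -> list[tuple[str, int, int, str]]:
    rows = []
    for t in genome.ssr_tracts:
        label = f"({t.unit}){t.copies}"
        if t.is_compound:
            label += f"({t.second_unit}){t.second_copies}"
        rows.append((t.chrom, t.start, t.end, label))
    return rows


def factors_bed_rows(genome: GenomeModel) -> list[tuple[str, int, int, str]]:
    y = genome.y_name
    return [(y, s, e, f) for f, (s, e) in sorted(genome.factor_loci.items())]


def write_panel(mutants: Sequence[MutantGenome], outdir: str | Path) -> Path:
    """Write per-mutant deletion BEDs plus a TSV manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "panel_manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("mutant\tphenotype\tdeletion_bed\n")
        for m in mutants:
            bed = outdir / f"{m.name}.deletions.bed"
            write_bed(
                [
                    (chrom, s, e, f"{m.name}_del")
                    for chrom, ivals in sorted(m.deletions.items())
                    for s, e in ivals
                ],
                bed,
            )
            fh.write(f"{m.name}\t{m.phenotype}\t{bed.name}\n")
    return manifest
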