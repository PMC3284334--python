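"""In-silico library construction, suppression PCR and the male-specificity screen.

The wet protocol modeled here: male genomic DNA is digested with one of three
blunt cutters (EcoRV, DraI, SspI) and ligated to a blunt adaptor whose short
strand is 3'-capped, so no polymerase extension can initiate from the adaptor
alone.  A compound-SSR primer paired with the adaptor primer AP2 therefore
amplifies only fragments carrying an internal SSR-primer site, oriented from
that site out to the adaptor-ligated end (suppression PCR).  Flank-specific
primers are then designed inside amplified fragments, and each
(specific primer, SSR partner) pair is screened on male (XY) versus female
(XX) templates: a product in the male only implies a Y-chromosome locus.

Primer binding uses a deterministic informatic model, not thermodynamics: the
3'-terminal ``seed_len`` bases must match exactly and at most ``max_mismatch``
mismatches are allowed elsewhere.  Band comparison mimics agarose resolution
by treating product lengths within a relative tolerance as one band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .genome import GenomeModel
from .primers import AP2, CompoundSSRPrimer

# Blunt cutters used for library construction; 6-mer palindromic sites cut at
# center (offset 3) leaving blunt ends, as required for blunt-adaptor ligation.
BLUNT_CUTTERS = {"EcoRV": "GATATC", "DraI": "TTTAAA", "SspI": "AATATT"}

MALE_SPECIFIC = "SmicSy_male_specific"
SHARED = "SmicS_shared"
NO_PRODUCT = "no_product"
NONSPECIFIC = "nonspecific"


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition_site: str
    cut_offset: int = 3

    def __post_init__(self) -> None:
        site = self.recognition_site
        if len(site) != 6 or site != reverse_complement(site):
            raise ValueError(f"{self.name}: site must be a palindromic 6-mer")
        if self.cut_offset != 3:
            raise ValueError(f"{self.name}: only blunt center cuts are supported")


ENZYMES = {name: RestrictionEnzyme(name, site) for name, site in BLUNT_CUTTERS.items()}


@dataclass(frozen=True)
class LibraryFragment:
    chrom: str
    start: int
    end: int
    sequence: str
    left_adaptor: bool = False
    right_adaptor: bool = False


@dataclass(frozen=True)
class BindingParams:
    """Primer-site acceptance rule: exact 3' seed, bounded mismatches elsewhere."""

    seed_len: int = 10
    max_mismatch: int = 2
    max_product: int = 3000
    min_product: int = 50

    def __post_init__(self) -> None:
        if self.seed_len <= 0:
            raise ValueError("seed_len must be positive")
        if not (0 < self.min_product < self.max_product):
            raise ValueError("require 0 < min_product < max_product")


@dataclass(frozen=True)
class Amplicon:
    """A suppression-PCR product: SSR primer at one end, adaptor tail at the other.

    ``start``/``end`` are genomic template coordinates (on the source
    chromosome) of the fragment-internal part of the product. ``sequence`` is
    written 5'->3' from the SSR primer and includes primer-derived ends.
    """

    chrom: str
    start: int
    end: int
    sequence: str
    fwd_primer: str
    rev_primer: str
    strand: str
    primer_len: int
    adaptor_tail_len: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def insert(self) -> str:
        """Template-derived interior: product minus primer end and adaptor tail."""
        return self.sequence[self.primer_len : len(self.sequence) - self.adaptor_tail_len]


def digest(
    sequence: str, enzyme: RestrictionEnzyme, chrom: str = "seq"
) -> list[LibraryFragment]:
    """Cut ``sequence`` at every recognition site (blunt, center cut).

    Fragments partition the input in order; a site-free sequence yields one
    fragment.  N never matches a site.
    """
    import Bio.Restriction

    bio_enzyme = getattr(Bio.Restriction, enzyme.name, None)
    if bio_enzyme is not None and str(bio_enzyme.site) == enzyme.recognition_site:
        from Bio.Seq import Seq

        cuts = [p - 1 for p in bio_enzyme.search(Seq(sequence), linear=True)]
    else:  # non-catalogued enzyme: direct site scan
        cuts = []
        pos = sequence.find(enzyme.recognition_site)
        while pos != -1:
            cuts.append(pos + enzyme.cut_offset)
            pos = sequence.find(enzyme.recognition_site, pos + 1)
    bounds = [0] + cuts + [len(sequence)]
    return [
        LibraryFragment(chrom=chrom, start=s, end=e, sequence=sequence[s:e])
        for s, e in zip(bounds, bounds[1:])
        if e > s
    ]


def ligate_adaptors(fragments: Iterable[LibraryFragment]) -> list[LibraryFragment]:
    """Flag both blunt ends adaptor-ligated.

    The capped adaptor strand cannot prime extension, so ligation confers no
    amplifiable site by itself; its consequence is the suppression rule in
    :func:`amplify_library` (products require an internal primer site).
    """
    return [
        LibraryFragment(
            chrom=f.chrom,
            start=f.start,
            end=f.end,
            sequence=f.sequence,
            left_adaptor=True,
            right_adaptor=True,
        )
        for f in fragments
    ]


def build_library(
    genome: GenomeModel, enzyme: RestrictionEnzyme
) -> list[LibraryFragment]:
    """Digest every chromosome and ligate adaptors."""
    frags: list[LibraryFragment] = []
    for chrom in genome.chromosomes:
        frags.extend(digest(genome.chromosomes[chrom], enzyme, chrom=chrom))
    return ligate_adaptors(frags)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _scan_plus(template: np.ndarray, primer: np.ndarray, params: BindingParams) -> np.ndarray:
    """Positions where the primer matches the template forward strand.

    The primer's 3' end is its last base; the seed is the 3'-terminal
    ``seed_len`` bases and must match exactly.
    """
    L = len(primer)
    if len(template) < L:
        return np.empty(0, dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(template, L)
    mism = windows != primer
    seed = min(params.seed_len, L)
    seed_ok = ~mism[:, L - seed :].any(axis=1)
    outside = mism[:, : L - seed].sum(axis=1)
    return np.flatnonzero(seed_ok & (outside <= params.max_mismatch))


def scan_binding_sites(
    template: str, primer: str, params: BindingParams
) -> list[tuple[int, str]]:
    """All primer binding sites on both strands of ``template``.

    A ``+`` site at position p means the primer anneals with its 5' end at p
    and extends rightward; a ``-`` site at p means the reverse complement of
    the primer equals template[p:p+len] (up to the mismatch rule) and the
    primer extends leftward.  Sorted by position then strand.
    """
    t = _encode(template.upper())
    p_fwd = _encode(primer.upper())
    p_rev = _encode(reverse_complement(primer.upper()))
    sites = [(int(pos), "+") for pos in _scan_plus(t, p_fwd, params)]
    # on the minus strand the primer's 3' seed maps to the *start* of the match
    L = len(p_rev)
    if len(t) >= L:
        windows = np.lib.stride_tricks.sliding_window_view(t, L)
        mism = windows != p_rev
        seed = min(params.seed_len, L)
        seed_ok = ~mism[:, :seed].any(axis=1)
        outside = mism[:, seed:].sum(axis=1)
        sites.extend(
            (int(pos), "-") for pos in np.flatnonzero(seed_ok & (outside <= params.max_mismatch))
        )
    return sorted(sites)


def _adaptor_tail() -> str:
    """Adaptor-derived 3' tail of every product: the amplified strand runs
    through the fragment end and into the adaptor up to and including the
    reverse complement of AP2."""
    from .primers import ADAPTOR_48 as adaptor

    k = adaptor.find(AP2)
    return reverse_complement(adaptor)[: len(adaptor) - k]


ADAPTOR_TAIL = _adaptor_tail()


def amplify_library(
    library: Sequence[LibraryFragment],
    ssr_primer: CompoundSSRPrimer,
    ap2: str = AP2,
    params: BindingParams | None = None,
) -> list[Amplicon]:
    """Suppression-PCR products of (SSR primer x AP2) over an adaptor-ligated library.

    One amplicon per (SSR-primer site, adaptor-ligated end) pair, oriented from
    the SSR primer toward the adaptor, within product-size limits.  Fragments
    lacking an internal SSR-primer site yield nothing: this is the suppression
    rule — the capped adaptor strand blocks adaptor-only priming, so AP2 alone
    produces no amplicons.
    """
    params = params or BindingParams()
    tail = ADAPTOR_TAIL
    pseq = ssr_primer.sequence
    if pseq == ap2:
        return []  # adaptor primer has no fragment-internal site by construction
    out: list[Amplicon] = []
    for frag in library:
        if not (frag.left_adaptor or frag.right_adaptor):
            continue
        for pos, strand in scan_binding_sites(frag.sequence, pseq, params):
            if strand == "+" and frag.right_adaptor:
                product = pseq + frag.sequence[pos + len(pseq) :] + tail
                tstart, tend = frag.start + pos, frag.end
            elif strand == "-" and frag.left_adaptor:
                # primer anneals at [pos, pos+L) on the forward strand; product
                # runs leftward: primer + revcomp of frag[:pos] + adaptor tail
                product = pseq + reverse_complement(frag.sequence[:pos]) + tail
                tstart, tend = frag.start, frag.start + pos + len(pseq)
            else:
                continue
            if params.min_product <= len(product) <= params.max_product:
                out.append(
                    Amplicon(
                        chrom=frag.chrom,
                        start=tstart,
                        end=tend,
                        sequence=product,
                        fwd_primer=ssr_primer.name,
                        rev_primer="AP2",
                        strand=strand,
                        primer_len=len(pseq),
                        adaptor_tail_len=len(tail),
                    )
                )
    return out


@dataclass(frozen=True)
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 30
    opt_len: int = 20
    gc_min: float = 30.0
    gc_max: float = 70.0
    # keep the primer clear of the compound-SSR end so the marker product has
    # nonzero insert between the two primers
    min_offset: int = 20


class NoValidPrimerError(ValueError):
    """No window of the amplicon flank satisfies the primer constraints."""


def _has_tandem_repeat(window: str, min_copies: int = 3) -> bool:
    """True if any trinucleotide unit repeats >= min_copies times in tandem."""
    for i in range(len(window) - 3 * min_copies + 1):
        unit = window[i : i + 3]
        if window[i : i + 3 * min_copies] == unit * min_copies:
            return True
    return False


def _gc(window: str) -> float:
    return 100.0 * (window.count("G") + window.count("C")) / len(window)


def design_specific_primer(
    amplicon: Amplicon, constraints: PrimerConstraints | None = None
) -> str:
    """Design a specific primer from the amplicon's unique flank.

    Scans the template-derived interior (primer- and adaptor-derived ends
    excluded) left to right starting ``min_offset`` nt past the compound-SSR
    end; at each start tries the optimal length first, then the remaining
    lengths ascending, and accepts the first window with acceptable GC and no
    internal trinucleotide tandem repeat.  The primer is the *reverse
    complement* of that window, so it points back toward the compound-SSR
    site and the (specific, SSR-partner) pair amplifies a defined product.
    Deterministic.
    """
    c = constraints or PrimerConstraints()
    flank = amplicon.insert
    if len(flank) < c.min_len + c.min_offset:
        raise NoValidPrimerError(
            f"flank of {len(flank)} nt too short for a {c.min_len} nt primer "
            f"at offset {c.min_offset}"
        )
    lengths = [c.opt_len] + [
        n for n in range(c.min_len, c.max_len + 1) if n != c.opt_len
    ]
    for start in range(c.min_offset, len(flank) - c.min_len + 1):
        for n in lengths:
            window = flank[start : start + n]
            if len(window) < n:
                continue
            if _has_tandem_repeat(window):
                continue
            if not (c.gc_min <= _gc(window) <= c.gc_max):
                continue
            return reverse_complement(window)
    raise NoValidPrimerError("no window satisfies primer constraints")


def pcr_products(
    genome: GenomeModel,
    fwd_primer: str,
    rev_primer: str,
    params: BindingParams | None = None,
    chromosomes: Sequence[str] | None = None,
) -> list[tuple[str, int, int, int]]:
    """Virtual PCR of a primer pair over whole chromosomes.

    Returns (chrom, start, end, product_length) for every opposing-orientation
    site pair within product-size limits, in both pair orientations.
    """
    params = params or BindingParams()
    out: list[tuple[str, int, int, int]] = []
    chroms = chromosomes if chromosomes is not None else list(genome.chromosomes)
    for chrom in chroms:
        template = genome.chromosomes[chrom]
        fsites = scan_binding_sites(template, fwd_primer, params)
        rsites = scan_binding_sites(template, rev_primer, params)
        for a_seq, a_sites, b_seq, b_sites in (
            (fwd_primer, fsites, rev_primer, rsites),
            (rev_primer, rsites, fwd_primer, fsites),
        ):
            plus = [p for p, s in a_sites if s == "+"]
            minus = [p for p, s in b_sites if s == "-"]
            for pf in plus:
                for pr in minus:
                    end = pr + len(b_seq)
                    length = end - pf
                    if pf <= pr and params.min_product <= length <= params.max_product:
                        out.append((chrom, pf, end, length))
    return sorted(set(out))


def band_lengths(products: Iterable[tuple[str, int, int, int]], tolerance: float = 0.05) -> list[int]:
    """Collapse product lengths into gel bands: lengths within ``tolerance``
    (relative) of a band's representative are merged, mimicking agarose
    resolution."""
    lengths = sorted(L for _, _, _, L in products)
    bands: list[int] = []
    for L in lengths:
        if not bands or L > bands[-1] * (1 + tolerance):
            bands.append(L)
    return bands


def score_sex_specificity(
    specific_primer: str,
    ssr_partner: CompoundSSRPrimer | str,
    male_genome: GenomeModel,
    female_genome: GenomeModel,
    params: BindingParams | None = None,
    band_tolerance: float = 0.05,
) -> tuple[str, int, int]:
    """Compare amplification between male and female templates.

    Returns (call, male_bands, female_bands).  A product in the male only is
    Y-specific (``SmicSy_male_specific``); one or two bands in both sexes is a
    shared autosomal/X/pseudoautosomal marker (``SmicS_shared``); more than two
    bands on either template is ``nonspecific`` (smeary pattern, discarded);
    no male product is ``no_product``.
    """
    partner = (
        ssr_partner.sequence if isinstance(ssr_partner, CompoundSSRPrimer) else ssr_partner
    )
    male = band_lengths(
        pcr_products(male_genome, specific_primer, partner, params), band_tolerance
    )
    female = band_lengths(
        pcr_products(female_genome, specific_primer, partner, params), band_tolerance
    )
    n_m, n_f = len(male), len(female)
    if n_m == 0:
        return (NO_PRODUCT, n_m, n_f)
    if n_m > 2 or n_f > 2:
        return (NONSPECIFIC, n_m, n_f)
    if n_f == 0:
        return (MALE_SPECIFIC, n_m, n_f)
    return (SHARED, n_m, n_f)
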