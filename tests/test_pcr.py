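"""Digestion, adaptor ligation, binding-site scanning, suppression-PCR
amplification, primer design and the male-specificity screen."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings, strategies as st

import ydelmap as y
from ydelmap import pcr
from ydelmap.genome import GenomeModel

from helpers import random_sequence


@pytest.mark.parametrize(
    "sequence, enzyme, expected",
    [
        ("AAAGATATCAAA", "EcoRV", ["AAAGAT", "ATCAAA"]),
        ("TTTAAATTTAAA", "DraI", ["TTT", "AAATTT", "AAA"]),
        ("ACGTACGTACGT", "SspI", ["ACGTACGTACGT"]),  # site-free: one fragment
    ],
)
def test_digest_cuts_at_recognition_sites(sequence, enzyme, expected):
    frags = pcr.digest(sequence, pcr.ENZYMES[enzyme])
    assert [f.sequence for f in frags] == expected
    assert "".join(f.sequence for f in frags) == sequence


@settings(max_examples=60, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=400), st.sampled_from(sorted(pcr.ENZYMES)))
def test_digest_partitions_input(sequence, enzyme_name):
    enzyme = pcr.ENZYMES[enzyme_name]
    frags = pcr.digest(sequence, enzyme)
    assert "".join(f.sequence for f in frags) == sequence
    bounds = [0] + [f.end for f in frags]
    assert bounds[-1] == len(sequence)
    # junctions reconstruct the recognition site
    for left, right in zip(frags, frags[1:]):
        junction = sequence[left.end - 3 : left.end + 3]
        assert junction == enzyme.recognition_site


def test_digest_ignores_n():
    assert len(pcr.digest("AAAGATNTCAAA", pcr.ENZYMES["EcoRV"])) == 1


def test_ligate_adaptors_flags_both_ends():
    assert pcr.ligate_adaptors([]) == []
    frags = pcr.ligate_adaptors(pcr.digest("AAAGATATCAAA", pcr.ENZYMES["EcoRV"]))
    assert all(f.left_adaptor and f.right_adaptor for f in frags)
    assert [f.sequence for f in frags] == ["AAAGAT", "ATCAAA"]


def test_ap2_alone_is_suppressed():
    """The capped adaptor strand blocks adaptor-only priming: amplification
    with AP2 as the sole primer yields nothing."""
    rng = np.random.default_rng(0)
    lib = pcr.ligate_adaptors(
        pcr.digest(random_sequence(rng, 5_000), pcr.ENZYMES["DraI"])
    )

    class _AP2AsPrimer:
        sequence = y.AP2
        name = "AP2"

    assert pcr.amplify_library(lib, _AP2AsPrimer()) == []


def test_scan_binding_sites_exact_and_reverse():
    params = pcr.BindingParams()
    primer = "CCATTTCAATTTGGGGTTTG"
    t_plus = "A" * 40 + primer + "G" * 40
    assert pcr.scan_binding_sites(t_plus, primer, params) == [(40, "+")]
    t_minus = "A" * 40 + reverse_complement(primer) + "G" * 40
    assert pcr.scan_binding_sites(t_minus, primer, params) == [(40, "-")]


def test_scan_binding_sites_seed_mismatch_rules():
    primer = "ACGTACGTACGTACGTACGT"
    # full-length seed: one internal mismatch kills the site
    strict = pcr.BindingParams(seed_len=len(primer), max_mismatch=2)
    template = "T" * 30 + "ACGTACGAACGTACGTACGT" + "T" * 30
    assert pcr.scan_binding_sites(template, primer, strict) == []
    # default 10-nt 3' seed: mismatch outside the seed is tolerated
    assert pcr.scan_binding_sites(template, primer, pcr.BindingParams()) == [(30, "+")]


def test_scan_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    params = pcr.BindingParams(seed_len=6, max_mismatch=2)
    for _ in range(20):
        template = random_sequence(rng, 300)
        primer = random_sequence(rng, 15)
        got = pcr.scan_binding_sites(template, primer, params)
        expected = []
        for p_seq, strand in ((primer, "+"), (reverse_complement(primer), "-")):
            for i in range(len(template) - len(p_seq) + 1):
                window = template[i : i + len(p_seq)]
                mism = [a != b for a, b in zip(window, p_seq)]
                seed = mism[-params.seed_len :] if strand == "+" else mism[: params.seed_len]
                rest = mism[: -params.seed_len] if strand == "+" else mism[params.seed_len :]
                if not any(seed) and sum(rest) <= params.max_mismatch:
                    expected.append((i, strand))
        assert got == sorted(expected)


def _planted_library(flank_left, site, flank_right):
    frag = pcr.LibraryFragment(
        chrom="chrT",
        start=0,
        end=len(flank_left + site + flank_right),
        sequence=flank_left + site + flank_right,
    )
    return pcr.ligate_adaptors([frag])


def test_amplify_emits_one_amplicon_per_site_adaptor_pair():
    rng = np.random.default_rng(1)
    primer = y.build_arrangement("SSR-4", "27M")
    lib = _planted_library(random_sequence(rng, 200), primer.sequence, random_sequence(rng, 300))
    amps = pcr.amplify_library(lib, primer)
    plus = [a for a in amps if a.strand == "+"]
    assert len(plus) == 1
    amp = plus[0]
    assert amp.sequence.startswith(primer.sequence)
    assert amp.sequence.endswith(pcr.ADAPTOR_TAIL)
    assert amp.insert in lib[0].sequence


def test_amplify_no_site_yields_nothing():
    rng = np.random.default_rng(2)
    primer = y.build_arrangement("SSR-4", "27M")
    lib = pcr.ligate_adaptors(
        [pcr.LibraryFragment("chrT", 0, 500, random_sequence(rng, 500))]
    )
    assert pcr.amplify_library(lib, primer) == []


def test_arrangements_of_one_combination_amplify_differently():
    """The four arrangement patterns of a combination target shifted registers
    of the repeat lattice, so one fragment generally yields different amplicon
    sets under 21S vs 27M."""
    rng = np.random.default_rng(3)
    site_27m = y.build_arrangement("SSR-4", "27M").sequence
    lib = _planted_library(random_sequence(rng, 150), site_27m, random_sequence(rng, 250))
    amps_27m = pcr.amplify_library(lib, y.build_arrangement("SSR-4", "27M"))
    amps_21s = pcr.amplify_library(lib, y.build_arrangement("SSR-4", "21S"))
    assert {a.sequence for a in amps_27m} != {a.sequence for a in amps_21s}


def test_design_specific_primer_is_deterministic_and_points_back():
    rng = np.random.default_rng(4)
    primer = y.build_arrangement("SSR-5", "27M")
    lib = _planted_library(random_sequence(rng, 100), primer.sequence, random_sequence(rng, 400))
    amp = [a for a in pcr.amplify_library(lib, primer) if a.strand == "+"][0]
    sp1 = pcr.design_specific_primer(amp)
    sp2 = pcr.design_specific_primer(amp)
    assert sp1 == sp2
    c = pcr.PrimerConstraints()
    assert c.min_len <= len(sp1) <= c.max_len
    gc = 100.0 * (sp1.count("G") + sp1.count("C")) / len(sp1)
    assert c.gc_min <= gc <= c.gc_max
    # points back toward the SSR end: its reverse complement is in the insert
    assert reverse_complement(sp1) in amp.insert


def test_design_fails_on_repeat_only_flank():
    primer = y.build_arrangement("SSR-4", "27M")
    amp = pcr.Amplicon(
        chrom="chrT", start=0, end=100,
        sequence=primer.sequence + "CAA" * 30 + pcr.ADAPTOR_TAIL,
        fwd_primer=primer.name, rev_primer="AP2", strand="+",
        primer_len=len(primer.sequence), adaptor_tail_len=len(pcr.ADAPTOR_TAIL),
    )
    with pytest.raises(pcr.NoValidPrimerError):
        pcr.design_specific_primer(amp)


def _two_sex_genomes(y_extra="", autosome_extra=""):
    rng = np.random.default_rng(7)
    auto = random_sequence(rng, 3_000) + autosome_extra + random_sequence(rng, 1_000)
    x = random_sequence(rng, 3_000)
    y_seq = random_sequence(rng, 2_000) + y_extra + random_sequence(rng, 1_000)
    male = GenomeModel(
        chromosomes={"chr1": auto, "chrX": x, "chrY": y_seq},
        sex_linkage={"chr1": "autosome", "chrX": "X", "chrY": "Y"},
    )
    female = GenomeModel(
        chromosomes={"chr1": auto, "chrX": x},
        sex_linkage={"chr1": "autosome", "chrX": "X"},
    )
    return male, female


def test_specificity_calls():
    partner = y.build_arrangement("SSR-4", "27M")
    flank = "GCTCCCAACACTACGCCTTAGATTACCGGATACCTGTTCACC"
    locus = partner.sequence + flank
    specific = reverse_complement(flank[-20:])

    male, female = _two_sex_genomes(y_extra=locus)
    call, n_m, n_f = pcr.score_sex_specificity(specific, partner, male, female)
    assert (call, n_m, n_f) == (pcr.MALE_SPECIFIC, 1, 0)

    male, female = _two_sex_genomes(autosome_extra=locus)
    call, n_m, n_f = pcr.score_sex_specificity(specific, partner, male, female)
    assert call == pcr.SHARED and n_m == n_f == 1

    male, female = _two_sex_genomes()
    call, n_m, n_f = pcr.score_sex_specificity(specific, partner, male, female)
    assert (call, n_m, n_f) == (pcr.NO_PRODUCT, 0, 0)


def test_specificity_call_depends_on_arrangement():
    """A Y locus carrying the 27M site is male-specific with the 27M partner
    but yields no product with the 21S arrangement of the same combination."""
    partner_27m = y.build_arrangement("SSR-4", "27M")
    partner_21s = y.build_arrangement("SSR-4", "21S")
    flank = "GCTCCCAACACTACGCCTTAGATTACCGGATACCTGTTCACC"
    locus = partner_27m.sequence + flank
    specific = reverse_complement(flank[-20:])
    male, female = _two_sex_genomes(y_extra=locus)
    call_27m, _, _ = pcr.score_sex_specificity(specific, partner_27m, male, female)
    call_21s, _, _ = pcr.score_sex_specificity(specific, partner_21s, male, female)
    assert call_27m == pcr.MALE_SPECIFIC
    assert call_21s == pcr.NO_PRODUCT


def test_band_merging_tolerance():
    products = [("c", 0, 100, 100), ("c", 5, 108, 103), ("c", 0, 400, 400)]
    assert pcr.band_lengths(products, tolerance=0.05) == [100, 400]
    assert pcr.band_lengths(products, tolerance=0.0) == [100, 103, 400]
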