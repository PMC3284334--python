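"""Compound-SSR primer set, suppression-PCR oligo constants and STS marker records.

A *compound* SSR primer targets the switch point between two tandemly arrayed
trinucleotide microsatellites, e.g. ``(CAG)4(CAA)3``.  The screen uses five
unit combinations, each in four arrangement patterns: two total lengths
(21 nt, 27 nt) and two structures — "simple" (pure repeats) and "modified"
(partial repeat units appended at the 5' and 3' ends, which shifts the
register of the 3' end relative to the repeat lattice).  The 5 x 4 product
gives the 20-primer set used for library amplification.

The modified-arrangement flanks do not follow a single generative rule across
combinations, so the full formula table is packaged as data and expanded
literally (:func:`build_arrangement`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

# Suppression-PCR oligos. The 48-mer blunt adaptor anneals to an 8-mer whose
# 3' end is capped by an amino residue: the cap blocks polymerase extension
# from the adaptor, so adaptor-only priming yields no product (modeled as the
# suppression rule in ydelmap.pcr). AP2 is the adaptor primer, an internal
# substring of the 48-mer.
ADAPTOR_48 = "GTAATACGACTCACTATAGGGCACGCGTGGTCGACGGCCCGGGCTGGT"
CAPPED_8 = "ACCAGCCC"
AP2 = "CTATAGGGCACGCGTGGT"

COMBINATIONS = ("SSR-1", "SSR-2", "SSR-3", "SSR-4", "SSR-5")
ARRANGEMENTS = ("21S", "21M", "27S", "27M")

_FORMULA_RE = re.compile(r"^([ACGT]*?)((?:\([ACGT]{3}\)\d+){2})([ACGT]*)$")
_BLOCK_RE = re.compile(r"\(([ACGT]{3})\)(\d+)")


@dataclass(frozen=True)
class AdaptorSet:
    """The three oligo constants of the adaptor-ligated library."""

    adaptor_48: str = ADAPTOR_48
    capped_8: str = CAPPED_8
    ap2: str = AP2

    def validate(self) -> None:
        if len(self.adaptor_48) != 48:
            raise ValueError("adaptor must be 48 nt")
        if len(self.capped_8) != 8:
            raise ValueError("capped oligo must be 8 nt")
        if self.capped_8 != reverse_complement(self.adaptor_48[-8:]):
            raise ValueError(
                "capped oligo must be the reverse complement of the adaptor 3' terminal 8 nt"
            )
        if self.ap2 not in self.adaptor_48:
            raise ValueError("AP2 must be a substring of the adaptor")


@dataclass(frozen=True)
class CompoundSSRPrimer:
    combination_id: str
    arrangement: str
    unit_a: str
    unit_b: str
    sequence: str

    @property
    def name(self) -> str:
        return f"{self.combination_id}_{self.arrangement}"

    def __post_init__(self) -> None:
        expected = 21 if self.arrangement.startswith("21") else 27
        if len(self.sequence) != expected:
            raise ValueError(
                f"{self.name}: sequence length {len(self.sequence)} != {expected}"
            )


@dataclass(frozen=True)
class STSMarkerRecord:
    """A sequence-tagged-site marker: specific forward primer + compound SSR partner.

    ``annealing_temp_C`` is wet-lab metadata (gradient-PCR optimum) and is
    never consulted by the in-silico binding model.
    """

    name: str
    specific_primer: str
    ssr_partner: str
    annealing_temp_C: int | None = None


def _formula_table() -> dict[tuple[str, str], tuple[str, str, str]]:
    """Map (combination, arrangement) -> (unit_a, unit_b, formula)."""
    table: dict[tuple[str, str], tuple[str, str, str]] = {}
    text = (
        resources.files("ydelmap.data").joinpath("compound_ssr_table.tsv").read_text()
    )
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        table[(row["combination"], row["arrangement"])] = (
            row["unit_a"],
            row["unit_b"],
            row["formula"],
        )
    return table


def expand_formula(formula: str) -> str:
    """Expand a repeat formula like ``AG(CAG)3(CAA)3C`` to its literal sequence."""
    m = _FORMULA_RE.match(formula)
    if m is None:
        raise ValueError(f"unparseable compound-SSR formula: {formula!r}")
    prefix, blocks, suffix = m.groups()
    body = "".join(unit * int(n) for unit, n in _BLOCK_RE.findall(blocks))
    return prefix + body + suffix


def build_arrangement(combination_id: str, arrangement: str) -> CompoundSSRPrimer:
    """Build one compound SSR primer from its packaged formula.

    Raises ``KeyError`` for an unknown combination or arrangement identifier.
    """
    try:
        unit_a, unit_b, formula = _formula_table()[(combination_id, arrangement)]
    except KeyError:
        raise KeyError(
            f"unknown compound-SSR primer {combination_id}_{arrangement}; "
            f"combinations: {COMBINATIONS}, arrangements: {ARRANGEMENTS}"
        ) from None
    return CompoundSSRPrimer(
        combination_id=combination_id,
        arrangement=arrangement,
        unit_a=unit_a,
        unit_b=unit_b,
        sequence=expand_formula(formula),
    )


def primer_by_name(name: str) -> CompoundSSRPrimer:
    """Resolve a name like ``SSR-4_27M``."""
    combination_id, _, arrangement = name.rpartition("_")
    return build_arrangement(combination_id, arrangement)


def enumerate_compound_primers(
    arrangement: str | None = None,
) -> list[CompoundSSRPrimer]:
    """Enumerate the full 5-combination x 4-arrangement primer set (20 primers).

    ``arrangement`` optionally restricts to a single arrangement pattern.
    """
    arrangements = (arrangement,) if arrangement else ARRANGEMENTS
    return [build_arrangement(c, a) for c in COMBINATIONS for a in arrangements]


def load_marker_table(path: str | Path) -> list[STSMarkerRecord]:
    """Load STS marker records from a TSV (name, specific_primer, ssr_partner, Ta).

    Lines starting with ``#`` are comments. Malformed rows raise ``ValueError``
    naming the offending row; an empty file returns an empty list with a warning.
    """
    lines = [
        ln
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        logger.warning("marker table %s is empty", path)
        return []
    header = lines[0].rstrip("\n").split("\t")
    required = {"name", "specific_primer", "ssr_partner"}
    if not required.issubset(header):
        raise ValueError(f"marker table {path}: header must contain {sorted(required)}")
    records = []
    for i, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise ValueError(f"marker table {path} row {i}: wrong field count")
        row = dict(zip(header, fields))
        primer = row["specific_primer"].upper()
        if not primer or set(primer) - set("ACGT"):
            raise ValueError(
                f"marker table {path} row {i} ({row['name']}): non-ACGT specific primer"
            )
        ta = row.get("annealing_temp_C")
        records.append(
            STSMarkerRecord(
                name=row["name"],
                specific_primer=primer,
                ssr_partner=row["ssr_partner"],
                annealing_temp_C=int(ta) if ta not in (None, "") else None,
            )
        )
    return records


def load_published_markers() -> list[STSMarkerRecord]:
    """The six published Y-specific markers (SmicSy1-6), partnered with
    SSR-4_27M or SSR-5_27M."""
    with resources.as_file(
        resources.files("ydelmap.data").joinpath("smicsy_markers.tsv")
    ) as p:
        return load_marker_table(p)


def write_primers_tsv(primers: Iterable[CompoundSSRPrimer], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tcombination\tarrangement\tunit_a\tunit_b\tsequence\n")
        for p in primers:
            fh.write(
                f"{p.name}\t{p.combination_id}\t{p.arrangement}\t"
                f"{p.unit_a}\t{p.unit_b}\t{p.sequence}\n"
            )


def read_primers_tsv(path: str | Path) -> list[CompoundSSRPrimer]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        out.append(
            CompoundSSRPrimer(
                combination_id=row["combination"],
                arrangement=row["arrangement"],
                unit_a=row["unit_a"],
                unit_b=row["unit_b"],
                sequence=row["sequence"],
            )
        )
    return out


def write_primers_fasta(primers: Iterable[CompoundSSRPrimer], path: str | Path) -> None:
    """FASTA export for use with external scanning tools."""
    with open(path, "w") as fh:
        for p in primers:
            fh.write(f">{p.name}\n{p.sequence}\n")
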