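"""End-to-end pipeline: simulate -> library -> amplify -> design -> screen ->
genotype -> order -> localize, plus the screen bookkeeping statistics.

Every stage is driven by a single :class:`PipelineConfig` and one master seed;
outputs are written in deterministic order so that two runs with the same
config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import genome as gn
from . import mapping as mp
from . import pcr
from . import primers as pr

logger = logging.getLogger(__name__)


@dataclass
class PanelConfig:
    n_mutants: int = 12
    mean_deletion: float = 15_000.0
    shape: float = 2.0
    no_deletion_fraction: float = 5 / 19


@dataclass
class ScreenConfig:
    max_amplicons_per_primer: int = 40
    max_candidates: int = 150
    max_panel_markers: int = 12
    band_tolerance: float = 0.05


@dataclass
class PipelineConfig:
    genome: gn.GenomeConfig = field(default_factory=gn.GenomeConfig)
    binding: pcr.BindingParams = field(default_factory=pcr.BindingParams)
    panel: PanelConfig = field(default_factory=PanelConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    primer_constraints: pcr.PrimerConstraints = field(
        default_factory=pcr.PrimerConstraints
    )
    ordering_method: str = "auto"
    max_exact_markers: int = 10
    seed: int = 42
    outdir: str = "ydelmap_out"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc_type, data):
            if data is None:
                return dc_type()
            kwargs = {}
            for f in dataclasses.fields(dc_type):
                if f.name in data:
                    kwargs[f.name] = data[f.name]
            return dc_type(**kwargs)

        g = build(gn.GenomeConfig, raw.get("genome"))
        # YAML has no tuples: restore interval types losslessly
        g.factor_fractions = {k: tuple(v) for k, v in g.factor_fractions.items()}
        g.m2_fraction = tuple(g.m2_fraction)
        return cls(
            genome=g,
            binding=build(pcr.BindingParams, raw.get("binding")),
            panel=build(PanelConfig, raw.get("panel")),
            screen=build(ScreenConfig, raw.get("screen")),
            primer_constraints=build(
                pcr.PrimerConstraints, raw.get("primer_constraints")
            ),
            ordering_method=raw.get("ordering_method", "auto"),
            max_exact_markers=raw.get("max_exact_markers", 10),
            seed=raw.get("seed", 42),
            outdir=raw.get("outdir", "ydelmap_out"),
        )


def demo_config(seed: int = 42, outdir: str = "ydelmap_out") -> PipelineConfig:
    """Small-genome configuration for quick, fully in-memory demonstration runs."""
    g = gn.GenomeConfig(
        autosome_lengths={"chr1": 30_000},
        x_length=40_000,
        y_length=60_000,
    )
    return PipelineConfig(
        genome=g,
        panel=PanelConfig(n_mutants=12, mean_deletion=6_000.0),
        seed=seed,
        outdir=outdir,
    )


@dataclass
class ScreenStatistics:
    """Bookkeeping of the male-specificity screen.

    The headline percentage is rounded to the nearest whole percent (matching
    how such yields are conventionally reported); the raw fraction is kept
    alongside.
    """

    n_tested: int
    n_male_specific: int
    n_shared: int = 0
    n_no_product: int = 0
    n_nonspecific: int = 0
    per_partner: pd.DataFrame | None = None

    @property
    def fraction_male_specific(self) -> float:
        return self.n_male_specific / self.n_tested if self.n_tested else 0.0

    @property
    def pct_male_specific(self) -> int:
        return round(100.0 * self.fraction_male_specific)

    @classmethod
    def from_counts(cls, n_tested: int, n_male_specific: int) -> "ScreenStatistics":
        return cls(n_tested=n_tested, n_male_specific=n_male_specific)


def compute_screen_statistics(results: pd.DataFrame) -> ScreenStatistics:
    """Summarize a screen result table (columns: marker, ssr_partner, call).

    Per-partner yields report, for each compound-SSR partner, how many
    candidates were tested with it and what percentage proved male-specific.
    """
    if results.empty:
        logger.warning("empty screen results; returning all-zero statistics")
        return ScreenStatistics(n_tested=0, n_male_specific=0)
    calls = results["call"]
    per = (
        results.assign(male_specific=(calls == pcr.MALE_SPECIFIC).astype(int))
        .groupby("ssr_partner", sort=True)
        .agg(tested=("call", "size"), male_specific=("male_specific", "sum"))
        .reset_index()
    )
    per["pct"] = (100.0 * per["male_specific"] / per["tested"]).round().astype(int)
    return ScreenStatistics(
        n_tested=len(results),
        n_male_specific=int((calls == pcr.MALE_SPECIFIC).sum()),
        n_shared=int((calls == pcr.SHARED).sum()),
        n_no_product=int((calls == pcr.NO_PRODUCT).sum()),
        n_nonspecific=int((calls == pcr.NONSPECIFIC).sum()),
        per_partner=per,
    )


class PipelineError(RuntimeError):
    def __init__(self, stage: str, path: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed (output dir {path}): {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole workflow; returns the run report (also written to disk).

    Outputs under ``config.outdir``: genome FASTAs and BEDs, the 20-primer set,
    amplicons, the screen TSV, the deletion panel TSV, the marker order, factor
    intervals, ``report.yaml`` and ``summary.txt``.  Fully reproducible from
    (config, seed).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    stage = "simulate"
    try:
        male = gn.simulate_genome(config.genome, seed=seed, sex="male")
        female = gn.female_from_male(male)
        gn.write_genome_fasta(male, out / "male_genome.fasta")
        gn.write_genome_fasta(female, out / "female_genome.fasta")
        gn.write_bed(gn.tracts_bed_rows(male), out / "ssr_tracts.bed")
        gn.write_bed(gn.factors_bed_rows(male), out / "factor_loci.bed")

        stage = "enumerate_primers"
        primer_set = pr.enumerate_compound_primers()
        pr.write_primers_tsv(primer_set, out / "compound_ssr_primers.tsv")
        pr.write_primers_fasta(primer_set, out / "compound_ssr_primers.fasta")

        stage = "amplify"
        libraries = [
            (name, pcr.build_library(male, pcr.ENZYMES[name]))
            for name in sorted(pcr.ENZYMES)
        ]
        amplicons: list[tuple[pcr.Amplicon, pr.CompoundSSRPrimer]] = []
        with open(out / "amplicons.bed", "w") as bed:
            for primer in primer_set:
                per_primer = []
                for enzyme_name, lib in libraries:
                    for amp in pcr.amplify_library(lib, primer, params=config.binding):
                        per_primer.append((amp, primer))
                for amp, p in per_primer[: config.screen.max_amplicons_per_primer]:
                    amplicons.append((amp, p))
                    bed.write(
                        f"{amp.chrom}\t{amp.start}\t{amp.end}\t{p.name}_{amp.strand}\n"
                    )

        stage = "design"
        candidates: list[tuple[str, pr.CompoundSSRPrimer]] = []
        seen: set[tuple[str, str]] = set()
        for amp, partner in amplicons:
            if len(candidates) >= config.screen.max_candidates:
                break
            try:
                specific = pcr.design_specific_primer(amp, config.primer_constraints)
            except pcr.NoValidPrimerError:
                continue
            key = (specific, partner.name)
            if key not in seen:
                seen.add(key)
                candidates.append((specific, partner))

        stage = "screen"
        partner_cache = {p.name: p for p in primer_set}
        rows = []
        for i, (specific, partner) in enumerate(candidates, 1):
            call, n_m, n_f = pcr.score_sex_specificity(
                specific,
                partner,
                male,
                female,
                config.binding,
                config.screen.band_tolerance,
            )
            rows.append(
                {
                    "marker": f"cand{i:04d}",
                    "specific_primer": specific,
                    "ssr_partner": partner.name,
                    "male_bands": n_m,
                    "female_bands": n_f,
                    "call": call,
                }
            )
        screen_df = pd.DataFrame(
            rows,
            columns=[
                "marker",
                "specific_primer",
                "ssr_partner",
                "male_bands",
                "female_bands",
                "call",
            ],
        )
        screen_df.to_csv(out / "screen.tsv", sep="\t", index=False)
        stats = compute_screen_statistics(screen_df)

        stage = "select_markers"
        specific_rows = screen_df[screen_df["call"] == pcr.MALE_SPECIFIC]
        markers = [
            pr.STSMarkerRecord(
                name=f"SySim{i}",
                specific_primer=row.specific_primer,
                ssr_partner=row.ssr_partner,
            )
            for i, row in enumerate(
                specific_rows.head(config.screen.max_panel_markers).itertuples(), 1
            )
        ]

        stage = "panel"
        mutants = gn.simulate_deletion_panel(
            male,
            config.panel.n_mutants,
            gn.DeletionSizeDist(config.panel.mean_deletion, config.panel.shape),
            seed=seed + 1,
            no_deletion_fraction=config.panel.no_deletion_fraction,
        )
        gn.write_panel(mutants, out / "panel")

        report: dict = {
            "seed": seed,
            "n_compound_primers": len(primer_set),
            "n_amplicons": len(amplicons),
            "n_candidates_screened": int(stats.n_tested),
            "n_smics_shared": int(stats.n_shared),
            "n_male_specific": int(stats.n_male_specific),
            "pct_male_specific": int(stats.pct_male_specific),
            "per_partner_yields": (
                stats.per_partner.to_dict(orient="records")
                if stats.per_partner is not None
                else []
            ),
            "n_mutants": len(mutants),
            "n_mutants_without_deletion": sum(
                1 for m in mutants if not m.y_deletions
            ),
        }

        if markers:
            stage = "genotype"
            panel = mp.genotype_panel(
                markers,
                mutants,
                config.binding,
                config.screen.band_tolerance,
                chromosomes=[male.y_name],
            )
            panel.to_tsv(out / "deletion_panel.tsv")

            stage = "order"
            results = mp.DeletionMapping(panel).fit(
                method=config.ordering_method,
                seed=seed,
                max_exact_markers=config.max_exact_markers,
            )
            results.marker_order.to_tsv(out / "marker_order.tsv")
            intervals = results.localize_all()
            with open(out / "factor_intervals.tsv", "w") as fh:
                fh.write(
                    "factor\tphenotype\tleft_flank\tcontained\tright_flank\t"
                    "supporting\tunexplained\n"
                )
                for name in sorted(intervals):
                    fi = intervals[name]
                    fh.write(
                        f"{fi.factor}\t{fi.phenotype}\t{fi.left_flank or '.'}\t"
                        f"{','.join(fi.contained_markers)}\t{fi.right_flank or '.'}\t"
                        f"{','.join(fi.supporting_mutants)}\t"
                        f"{','.join(fi.unexplained_mutants) or '.'}\n"
                    )
            (out / "summary.txt").write_text(results.summary() + "\n")
            report.update(
                {
                    "n_panel_markers": len(panel.markers),
                    "ordering_objective": int(results.objective),
                    "ordering_exact": bool(results.exact),
                    "factors_localized": sorted(intervals),
                }
            )
        else:
            logger.warning("no male-specific markers found; skipping panel mapping")
            report.update(
                {"n_panel_markers": 0, "ordering_objective": None, "factors_localized": []}
            )

        with open(out / "report.yaml", "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=True)
        # the run location is not a parameter: keep the dumped config
        # byte-identical across output directories
        cfg_dict = asdict(config)
        cfg_dict.pop("outdir", None)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg_dict, fh, sort_keys=True)
        return report
    except Exception as exc:  # annotate failures with the stage that raised
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(out), exc) from exc
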