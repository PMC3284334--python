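"""Deletion-panel genotyping and marker ordering by deletion-site minimization.

A deletion panel is a binary mutant x marker matrix (1 = fragment amplified,
0 = marker deleted).  If every mutant carries contiguous Y deletions, there is
a marker order in which each mutant's 0s form contiguous runs (the
consecutive-ones property).  The mapping objective is therefore the total
number of deletion blocks — maximal runs of 0s per mutant row, summed over
mutants — and marker order is inferred by minimizing it: exactly by
branch-and-bound for small panels, or by greedy construction plus 2-opt for
larger ones.  Sex-determination factors are then localized to the
intersection of the deleted spans of the mutants in a phenotype class,
bounded by the nearest markers retained by all of them.

The inference is exposed statsmodels-style: :class:`DeletionMapping` is the
model over a panel; ``fit()`` returns :class:`DeletionMappingResults` with the
order, objective, per-mutant diagnostics, ``localize()`` and ``summary()``.

The orientation of an inferred order is arbitrary: reversing it leaves the
objective unchanged, so results are canonicalized to the lexicographically
smaller of the two directions and flagged accordingly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, MutantGenome, WT_MALE
from .pcr import BindingParams, band_lengths, pcr_products
from .primers import STSMarkerRecord, primer_by_name

REDUCED = "R"


class IncompatiblePanelError(ValueError):
    """Phenotype-class deletions share no common marker (suggests >1 locus)."""


@dataclass
class DeletionPanel:
    """Presence/absence calls with per-mutant phenotypes.

    ``calls``: DataFrame, index = mutant names, columns = marker names, values
    in {0, 1}.  ``reduced`` flags cells where a fragment amplified but was
    smaller than in the wild-type male control; such cells are *present* (1)
    for ordering — the primer sites remain — with the annotation preserved for
    reporting.
    """

    calls: pd.DataFrame
    phenotypes: pd.Series
    reduced: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        calls = self.calls
        if calls.index.has_duplicates or calls.columns.has_duplicates:
            raise ValueError("mutant and marker names must be unique")
        values = calls.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("calls must be 0/1")
        self.calls = calls.astype(np.int8)
        self.phenotypes = self.phenotypes.reindex(calls.index)
        if self.reduced is None:
            self.reduced = pd.DataFrame(
                False, index=calls.index, columns=calls.columns
            )
        # a designated control row must amplify everywhere; phenotypically
        # wild-type mutants may still lose markers (deletion between factors)
        for mut in calls.index:
            if str(mut).upper() in ("WT", "WT_MALE") and not (calls.loc[mut] == 1).all():
                raise ValueError(f"wild-type male control row {mut} must be all-present")

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def mutants(self) -> list[str]:
        return list(self.calls.index)

    def deleted_counts(self) -> pd.Series:
        """Markers deleted per mutant."""
        return (self.calls == 0).sum(axis=1)

    def informative(self) -> "DeletionPanel":
        """Drop all-present mutants: they contribute 0 blocks under every order."""
        keep = (self.calls == 0).any(axis=1)
        return DeletionPanel(
            calls=self.calls.loc[keep],
            phenotypes=self.phenotypes.loc[keep],
            reduced=self.reduced.loc[keep],
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("mutant\tphenotype\t" + "\t".join(self.markers) + "\n")
            for mut in self.mutants:
                cells = [
                    REDUCED
                    if self.reduced.at[mut, mk]
                    else str(int(self.calls.at[mut, mk]))
                    for mk in self.markers
                ]
                fh.write(f"{mut}\t{self.phenotypes.loc[mut]}\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DeletionPanel":
        lines = [
            ln
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        header = lines[0].split("\t")
        if header[:2] != ["mutant", "phenotype"]:
            raise ValueError(f"panel {path}: first columns must be mutant, phenotype")
        markers = header[2:]
        rows, phenos, red = {}, {}, {}
        for ln in lines[1:]:
            fields = ln.split("\t")
            if len(fields) != len(header):
                raise ValueError(f"panel {path}: row {fields[0]!r} has wrong width")
            mut = fields[0]
            phenos[mut] = fields[1]
            cells = fields[2:]
            rows[mut] = [1 if c in ("1", REDUCED) else 0 for c in cells]
            red[mut] = [c == REDUCED for c in cells]
        calls = pd.DataFrame.from_dict(rows, orient="index", columns=markers)
        return cls(
            calls=calls,
            phenotypes=pd.Series(phenos),
            reduced=pd.DataFrame.from_dict(red, orient="index", columns=markers),
        )


def load_synthetic_panel() -> DeletionPanel:
    """The packaged 19-mutant x 25-marker panel (a constructed stand-in for the
    published figure; see the file header for the facts it enforces)."""
    from importlib import resources

    with resources.as_file(
        resources.files("ydelmap.data").joinpath("deletion_panel_synthetic.tsv")
    ) as p:
        return DeletionPanel.from_tsv(p)


# --------------------------------------------------------------------------
# Objective
# --------------------------------------------------------------------------


def _zeros_matrix(panel: DeletionPanel) -> np.ndarray:
    return (panel.calls.to_numpy() == 0)


def _objective_tables(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F[j] = #rows deleted at marker j; T[a, b] = #rows with 1 at a and 0 at b.

    Total blocks under order o = F[o0] + sum_k T[o_{k-1}, o_k].
    """
    Zf = Z.astype(np.int32)
    F = Zf.sum(axis=0)
    T = (1 - Zf).T @ Zf
    return F, T


def count_deletion_blocks(order: Sequence[str], panel: DeletionPanel) -> int:
    """Total number of maximal runs of 0s over all mutant rows under ``order``."""
    if sorted(order) != sorted(panel.markers):
        raise ValueError("order must be a permutation of the panel markers")
    Z = _zeros_matrix(panel)[:, [panel.markers.index(m) for m in order]]
    starts = Z.copy()
    starts[:, 1:] &= ~Z[:, :-1]
    return int(starts.sum())


def per_mutant_blocks(order: Sequence[str], panel: DeletionPanel) -> dict[str, int]:
    idx = [panel.markers.index(m) for m in order]
    Z = _zeros_matrix(panel)[:, idx]
    starts = Z.copy()
    starts[:, 1:] &= ~Z[:, :-1]
    counts = starts.sum(axis=1)
    return {mut: int(c) for mut, c in zip(panel.mutants, counts)}


def _transition_tables(Z: np.ndarray) -> np.ndarray:
    """T2[a, b] = #rows whose call differs between markers a and b (for the
    alternative breakpoint-count objective)."""
    Zf = Z.astype(np.int32)
    return (Zf[:, :, None] != Zf[:, None, :]).sum(axis=0)


def count_breakpoints(order: Sequence[str], panel: DeletionPanel) -> int:
    """Alternative objective: total adjacent call changes (internal boundaries)."""
    if sorted(order) != sorted(panel.markers):
        raise ValueError("order must be a permutation of the panel markers")
    idx = [panel.markers.index(m) for m in order]
    Z = _zeros_matrix(panel)[:, idx]
    return int((Z[:, 1:] != Z[:, :-1]).sum())


# --------------------------------------------------------------------------
# Ordering
# --------------------------------------------------------------------------


@dataclass
class MarkerOrder:
    order: list[str]
    objective: int
    exact: bool
    per_mutant_blocks: dict[str, int] = field(default_factory=dict)
    orientation_arbitrary: bool = True

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tmarker\n")
            for i, m in enumerate(self.order, 1):
                fh.write(f"{i}\t{m}\n")


def _canonical(names: Sequence[str]) -> list[str]:
    rev = list(reversed(names))
    return list(names) if list(names) <= rev else rev


class _TooManyMarkers(ValueError):
    pass


def order_markers_exact(panel: DeletionPanel, max_markers: int = 10) -> MarkerOrder:
    """Globally minimize total deletion blocks by branch-and-bound.

    Markers are explored in sorted-name order so the returned permutation is
    the lexicographically smallest global minimizer; with reversal symmetry
    this also canonicalizes orientation.  Refuses panels with more than
    ``max_markers`` markers (factorial search space) — use
    :func:`order_markers_heuristic` instead.
    """
    markers = sorted(panel.markers)
    n = len(markers)
    if n > max_markers:
        raise _TooManyMarkers(
            f"{n} markers exceeds max_markers={max_markers}; use the heuristic solver"
        )
    info = panel.informative()
    if not info.mutants or n == 1:
        order = markers
        return MarkerOrder(
            order=order,
            objective=count_deletion_blocks(order, panel),
            exact=True,
            per_mutant_blocks=per_mutant_blocks(order, panel),
        )
    Z = _zeros_matrix(info)[:, [panel.markers.index(m) for m in markers]]
    m_rows = Z.shape[0]
    remaining = Z.sum(axis=1).astype(np.int32)

    # upper bound from the heuristic to prune early
    heur = order_markers_heuristic(panel, seed=0)
    best = heur.objective

    last_zero = np.zeros(m_rows, dtype=bool)
    used = np.zeros(n, dtype=bool)

    def lower_bound(completed: int, last_zero, remaining) -> int:
        open_or_pending = last_zero | (remaining > 0)
        return completed + int(open_or_pending.sum())

    best_perm: list[int] | None = None

    def dfs(prefix: list[int], completed: int, last_zero, remaining, find_first: bool):
        nonlocal best, best_perm
        if len(prefix) == n:
            cost = completed + int(last_zero.sum())
            if find_first:
                if cost == best and best_perm is None:
                    best_perm = prefix.copy()
            elif cost < best:
                best = cost
            return
        for j in range(n):
            if used[j]:
                continue
            col = Z[:, j]
            closed = last_zero & ~col
            nc = completed + int(closed.sum())
            nlz = col.copy()
            nrem = remaining - col
            lb = lower_bound(nc, nlz, nrem)
            if lb > best or (not find_first and lb == best) or (
                find_first and best_perm is not None
            ):
                if find_first and best_perm is not None:
                    return
                continue
            used[j] = True
            prefix.append(j)
            dfs(prefix, nc, nlz, nrem, find_first)
            prefix.pop()
            used[j] = False

    # pass 1: optimal objective; pass 2: first (lex-smallest) permutation attaining it
    dfs([], 0, last_zero, remaining, find_first=False)
    dfs([], 0, last_zero, remaining, find_first=True)
    if best_perm is None:  # heuristic order already optimal and lex search found none better
        order = _canonical(heur.order)
    else:
        order = [markers[j] for j in best_perm]
    return MarkerOrder(
        order=order,
        objective=best,
        exact=True,
        per_mutant_blocks=per_mutant_blocks(order, panel),
    )


def _objective_from_tables(order_idx: np.ndarray, F: np.ndarray, T: np.ndarray) -> int:
    return int(F[order_idx[0]] + T[order_idx[:-1], order_idx[1:]].sum())


def _two_opt(order_idx: np.ndarray, F: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Best-improvement 2-opt (segment reversal) until a local optimum."""
    n = len(order_idx)
    cur = _objective_from_tables(order_idx, F, T)
    improved = True
    while improved:
        improved = False
        best_delta, best_move = 0, None
        for i in range(n - 1):
            for j in range(i + 1, n):
                cand = order_idx.copy()
                cand[i : j + 1] = cand[i : j + 1][::-1]
                delta = _objective_from_tables(cand, F, T) - cur
                if delta < best_delta:
                    best_delta, best_move = delta, (i, j)
        if best_move is not None:
            i, j = best_move
            order_idx[i : j + 1] = order_idx[i : j + 1][::-1]
            cur += best_delta
            improved = True
    return order_idx


def _greedy_path(S: np.ndarray) -> list[int]:
    """Greedy path through the co-deletion similarity graph: seed with the most
    co-deleted pair, then repeatedly attach the marker most similar to either
    endpoint."""
    n = S.shape[0]
    if n == 1:
        return [0]
    S = S.astype(np.int64).copy()
    np.fill_diagonal(S, -1)
    a, b = np.unravel_index(np.argmax(S), S.shape)
    path = [int(a), int(b)]
    unused = set(range(n)) - set(path)
    while unused:
        head, tail = path[0], path[-1]
        cand = sorted(unused)
        head_sim = [S[head, j] for j in cand]
        tail_sim = [S[tail, j] for j in cand]
        hi, ti = int(np.argmax(head_sim)), int(np.argmax(tail_sim))
        if head_sim[hi] > tail_sim[ti]:
            path.insert(0, cand[hi])
            unused.discard(cand[hi])
        else:
            path.append(cand[ti])
            unused.discard(cand[ti])
    return path


def order_markers_heuristic(
    panel: DeletionPanel, seed: int = 0, n_restarts: int = 10
) -> MarkerOrder:
    """Greedy adjacency construction plus 2-opt refinement, with seeded random
    restarts.  Deterministic given (panel, seed); objective >= the exact
    optimum by construction."""
    markers = sorted(panel.markers)
    n = len(markers)
    if n < 2:
        order = markers
        return MarkerOrder(
            order=order,
            objective=count_deletion_blocks(order, panel),
            exact=False,
            per_mutant_blocks=per_mutant_blocks(order, panel),
        )
    info = panel.informative()
    if not info.mutants:
        return MarkerOrder(
            order=markers,
            objective=0,
            exact=False,
            per_mutant_blocks=per_mutant_blocks(markers, panel),
        )
    col_idx = [panel.markers.index(m) for m in markers]
    Z = _zeros_matrix(info)[:, col_idx]
    F, T = _objective_tables(Z)
    S = Z.astype(np.int64).T @ Z.astype(np.int64)  # co-deletion counts

    rng = np.random.default_rng(seed)
    best_idx: np.ndarray | None = None
    best_obj = np.inf
    for r in range(max(1, n_restarts)):
        start = (
            np.array(_greedy_path(S)) if r == 0 else rng.permutation(n)
        )
        refined = _two_opt(start.copy(), F, T)
        obj = _objective_from_tables(refined, F, T)
        if obj < best_obj:
            best_obj, best_idx = obj, refined
    order = _canonical([markers[j] for j in best_idx])
    return MarkerOrder(
        order=order,
        objective=int(best_obj),
        exact=False,
        per_mutant_blocks=per_mutant_blocks(order, panel),
    )


def order_markers(
    panel: DeletionPanel,
    method: str = "auto",
    seed: int = 0,
    max_exact_markers: int = 10,
) -> MarkerOrder:
    if method == "exact":
        return order_markers_exact(panel, max_markers=max_exact_markers)
    if method == "heuristic":
        return order_markers_heuristic(panel, seed=seed)
    if method == "auto":
        if len(panel.markers) <= max_exact_markers:
            return order_markers_exact(panel, max_markers=max_exact_markers)
        return order_markers_heuristic(panel, seed=seed)
    raise ValueError(f"unknown ordering method {method!r}")


# --------------------------------------------------------------------------
# Factor localization
# --------------------------------------------------------------------------

PHENOTYPE_FACTOR = {
    "hermaphrodite": "GSF",
    "ESS": "SPF",
    "ISS": "M2",
    "LSS": "MFF",
}


def _factor_for(phenotype: str) -> str:
    if phenotype.startswith("hermaphrodite"):
        return "GSF"
    return PHENOTYPE_FACTOR.get(phenotype, phenotype)


@dataclass
class FactorInterval:
    factor: str
    phenotype: str
    contained_markers: list[str]
    left_flank: str | None
    right_flank: str | None
    supporting_mutants: list[str]
    unexplained_mutants: list[str]

    def __str__(self) -> str:
        left = self.left_flank or "(end)"
        right = self.right_flank or "(end)"
        span = ", ".join(self.contained_markers)
        return f"{self.factor} [{self.phenotype}]: {left} < [{span}] < {right}"


def localize_factor(
    panel: DeletionPanel,
    order: MarkerOrder | Sequence[str],
    phenotype: str,
    factor: str | None = None,
) -> FactorInterval:
    """Localize a factor to the intersection of the deleted spans of its
    phenotype class, under the given marker order.

    Mutants of the class with no deletions cannot place the factor and are
    reported as unexplained.  Hermaphrodite sub-classes (complete/incomplete,
    composite labels) are pooled by prefix match.  An empty intersection
    raises :class:`IncompatiblePanelError` naming the incompatible mutants —
    evidence for more than one underlying locus.
    """
    names = list(order.order) if isinstance(order, MarkerOrder) else list(order)
    if sorted(names) != sorted(panel.markers):
        raise ValueError("order must be a permutation of the panel markers")
    pstr = panel.phenotypes.astype(str)
    if phenotype == "hermaphrodite":  # generic class pools complete/incomplete/composite
        is_class = pstr.str.startswith("hermaphrodite")
    elif phenotype in ("ESS", "ISS", "LSS"):
        is_class = pstr.str.split("+").apply(lambda parts: phenotype in parts)
    else:
        is_class = pstr == phenotype
    class_mutants = [m for m in panel.mutants if is_class.loc[m]]
    if not class_mutants:
        raise ValueError(f"no mutants with phenotype {phenotype!r}")
    calls = panel.calls[names]
    supporting = [m for m in class_mutants if (calls.loc[m] == 0).any()]
    unexplained = [m for m in class_mutants if m not in supporting]
    if not supporting:
        raise ValueError(
            f"phenotype {phenotype!r} has no mutants with Y deletions; "
            f"unexplained: {unexplained}"
        )
    deleted = (calls.loc[supporting] == 0).all(axis=0)
    common = [mk for mk in names if deleted[mk]]
    if not common:
        raise IncompatiblePanelError(
            f"deleted spans of {supporting} share no marker; the class may "
            "reflect more than one locus"
        )
    positions = [names.index(mk) for mk in common]
    lo, hi = min(positions), max(positions)
    retained_by_all = (calls.loc[supporting] == 1).all(axis=0)
    left_flank = next(
        (names[i] for i in range(lo - 1, -1, -1) if retained_by_all[names[i]]), None
    )
    right_flank = next(
        (names[i] for i in range(hi + 1, len(names)) if retained_by_all[names[i]]), None
    )
    return FactorInterval(
        factor=factor or _factor_for(phenotype),
        phenotype=phenotype,
        contained_markers=[names[i] for i in range(lo, hi + 1)],
        left_flank=left_flank,
        right_flank=right_flank,
        supporting_mutants=supporting,
        unexplained_mutants=unexplained,
    )


# --------------------------------------------------------------------------
# Genotyping
# --------------------------------------------------------------------------


def genotype_panel(
    markers: Sequence[STSMarkerRecord],
    mutants: Sequence[MutantGenome],
    params: BindingParams | None = None,
    band_tolerance: float = 0.05,
    chromosomes: Sequence[str] | None = None,
) -> DeletionPanel:
    """Score each marker on each mutant genome by virtual PCR.

    A cell is 0 iff the marker yields no product on the mutant; if a product
    exists but every band is shorter than the wild-type band beyond the band
    tolerance, the cell is 1 with a reduced-size annotation (a deletion
    interior to the amplicon that spares both primer sites).  A marker that
    fails on the wild-type male base genome is invalid for the panel.
    """
    params = params or BindingParams()
    if not mutants:
        raise ValueError("empty mutant panel")
    base = mutants[0].base
    partner_seq = {
        rec.name: primer_by_name(rec.ssr_partner).sequence for rec in markers
    }
    wt_bands: dict[str, list[int]] = {}
    for rec in markers:
        bands = band_lengths(
            pcr_products(base, rec.specific_primer, partner_seq[rec.name], params, chromosomes),
            band_tolerance,
        )
        if not bands:
            raise ValueError(
                f"marker {rec.name} yields no product on the wild-type male genome"
            )
        wt_bands[rec.name] = bands

    calls, reduced, phenos = {}, {}, {}
    for mut in mutants:
        mut_model = GenomeModel(
            chromosomes={
                c: mut.chromosome_sequence(c) for c in mut.base.chromosomes
            },
            sex_linkage=dict(mut.base.sex_linkage),
        )
        row, rrow = [], []
        for rec in markers:
            bands = band_lengths(
                pcr_products(
                    mut_model, rec.specific_primer, partner_seq[rec.name], params, chromosomes
                ),
                band_tolerance,
            )
            if not bands:
                row.append(0)
                rrow.append(False)
            else:
                matches_wt = any(
                    abs(b - w) <= band_tolerance * w
                    for b in bands
                    for w in wt_bands[rec.name]
                )
                row.append(1)
                rrow.append(not matches_wt and max(bands) < max(wt_bands[rec.name]))
        calls[mut.name] = row
        reduced[mut.name] = rrow
        phenos[mut.name] = mut.phenotype

    names = [rec.name for rec in markers]
    return DeletionPanel(
        calls=pd.DataFrame.from_dict(calls, orient="index", columns=names),
        phenotypes=pd.Series(phenos),
        reduced=pd.DataFrame.from_dict(reduced, orient="index", columns=names),
    )


def genotype_by_position(
    marker_loci: Mapping[str, tuple[int, int]],
    mutants: Sequence[MutantGenome],
) -> DeletionPanel:
    """Fast coordinate-based genotyping: a marker is absent iff its Y locus
    overlaps a deletion.  Equivalent to PCR genotyping when marker loci are the
    amplicon spans and deletions either hit a primer site or not at all; used
    for large simulated panels where full binding-site scanning is unnecessary.
    """
    calls, phenos = {}, {}
    names = list(marker_loci)
    for mut in mutants:
        dels = mut.y_deletions
        calls[mut.name] = [
            0 if any(s < e2 and s2 < e for s2, e2 in dels) else 1
            for s, e in (marker_loci[m] for m in names)
        ]
        phenos[mut.name] = mut.phenotype
    return DeletionPanel(
        calls=pd.DataFrame.from_dict(calls, orient="index", columns=names),
        phenotypes=pd.Series(phenos),
    )


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------


class DeletionMapping:
    """Marker-order model over a deletion panel.

    Parameters
    ----------
    panel : DeletionPanel
        Presence/absence matrix with phenotypes.
    objective : {"blocks", "breakpoints"}
        "blocks" (default) minimizes the total number of deletion blocks;
        "breakpoints" minimizes adjacent call changes (alternative reading of
        deletion-site minimization; heuristic solver only).
    """

    def __init__(self, panel: DeletionPanel, objective: str = "blocks"):
        if objective not in ("blocks", "breakpoints"):
            raise ValueError("objective must be 'blocks' or 'breakpoints'")
        self.panel = panel
        self.objective = objective

    @classmethod
    def from_dataframe(
        cls,
        calls: pd.DataFrame,
        phenotypes: Mapping[str, str] | pd.Series,
        **kwargs,
    ) -> "DeletionMapping":
        return cls(DeletionPanel(calls=calls, phenotypes=pd.Series(phenotypes)), **kwargs)

    def fit(
        self,
        method: str = "auto",
        seed: int = 0,
        max_exact_markers: int = 10,
    ) -> "DeletionMappingResults":
        if self.objective == "breakpoints":
            order = self._fit_breakpoints(seed)
        else:
            order = order_markers(
                self.panel, method=method, seed=seed, max_exact_markers=max_exact_markers
            )
        return DeletionMappingResults(self, order)

    def _fit_breakpoints(self, seed: int) -> MarkerOrder:
        markers = sorted(self.panel.markers)
        info = self.panel.informative()
        Z = _zeros_matrix(info)[:, [self.panel.markers.index(m) for m in markers]]
        T2 = _transition_tables(Z)
        F0 = np.zeros(len(markers), dtype=np.int64)
        rng = np.random.default_rng(seed)
        best_idx, best_obj = None, np.inf
        for r in range(10):
            start = np.arange(len(markers)) if r == 0 else rng.permutation(len(markers))
            refined = _two_opt(start.copy(), F0, T2)
            obj = _objective_from_tables(refined, F0, T2)
            if obj < best_obj:
                best_obj, best_idx = obj, refined
        order = _canonical([markers[j] for j in best_idx])
        return MarkerOrder(
            order=order,
            objective=int(best_obj),
            exact=False,
            per_mutant_blocks=per_mutant_blocks(order, self.panel),
        )


class DeletionMappingResults:
    """Fitted marker order with diagnostics and factor localization."""

    def __init__(self, model: DeletionMapping, marker_order: MarkerOrder):
        self.model = model
        self.marker_order = marker_order

    @property
    def order(self) -> list[str]:
        return self.marker_order.order

    @property
    def objective(self) -> int:
        return self.marker_order.objective

    @property
    def exact(self) -> bool:
        return self.marker_order.exact

    @property
    def per_mutant_blocks(self) -> dict[str, int]:
        return self.marker_order.per_mutant_blocks

    def localize(self, phenotype: str, factor: str | None = None) -> FactorInterval:
        return localize_factor(self.model.panel, self.marker_order, phenotype, factor)

    def localize_all(self) -> dict[str, FactorInterval]:
        """Localize every factor whose phenotype class has deleted mutants."""
        out: dict[str, FactorInterval] = {}
        for pheno in ("hermaphrodite", "ESS", "ISS", "LSS"):
            try:
                fi = self.localize(pheno)
            except (ValueError, IncompatiblePanelError):
                continue
            out[fi.factor] = fi
        return out

    def summary(self) -> str:
        panel = self.model.panel
        lines = [
            "Deletion-panel marker ordering",
            "==============================",
            f"markers: {len(panel.markers)}   mutants: {len(panel.mutants)} "
            f"({len(panel.informative().mutants)} with deletions)",
            f"solver: {'exact (branch-and-bound)' if self.exact else 'heuristic (greedy + 2-opt)'}",
            f"objective ({self.model.objective}): {self.objective}",
            "orientation: arbitrary up to reversal",
            "",
            "order: " + " - ".join(self.order),
            "",
            "blocks per mutant:",
        ]
        deleted = panel.deleted_counts()
        for mut in panel.mutants:
            lines.append(
                f"  {mut:>10s}  phenotype={panel.phenotypes.loc[mut]:<28s} "
                f"deleted={int(deleted.loc[mut]):>3d}  blocks={self.per_mutant_blocks.get(mut, 0)}"
            )
        for fi in self.localize_all().values():
            lines.append("")
            lines.append(f"  {fi}")
            if fi.unexplained_mutants:
                lines.append(f"    unexplained (no deletion): {', '.join(fi.unexplained_mutants)}")
        return "\n".join(lines)
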