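"""Deletion-panel construction, block counting, marker ordering and factor
localization."""

import itertools

import numpy as np
import pandas as pd
import pytest

import ydelmap as y
from ydelmap import mapping as mp

from helpers import brute_force_blocks, random_panel, staircase_panel


def make_panel(rows: dict[str, list[int]], phenotypes: dict[str, str] | None = None):
    markers = [f"M{j:02d}" for j in range(len(next(iter(rows.values()))))]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=markers)
    phen = pd.Series(phenotypes or {m: "x" for m in rows})
    return mp.DeletionPanel(calls=df, phenotypes=phen)


# ---------------------------------------------------------------- panel


def test_panel_rejects_non_binary_and_duplicates():
    with pytest.raises(ValueError, match="0/1"):
        make_panel({"m0": [0, 2, 1]})
    df = pd.DataFrame([[1, 1]], index=["m0"], columns=["A", "A"])
    with pytest.raises(ValueError, match="unique"):
        mp.DeletionPanel(calls=df, phenotypes=pd.Series({"m0": "x"}))


def test_control_row_must_be_all_present():
    with pytest.raises(ValueError, match="control"):
        make_panel({"WT": [1, 0, 1]}, {"WT": "WT_male"})


def test_panel_tsv_round_trip_preserves_reduced_cells(tmp_path):
    panel = y.load_synthetic_panel()
    path = tmp_path / "panel.tsv"
    panel.to_tsv(path)
    back = mp.DeletionPanel.from_tsv(path)
    assert back.calls.equals(panel.calls)
    assert back.phenotypes.equals(panel.phenotypes)
    assert back.reduced.equals(panel.reduced)
    assert back.reduced.to_numpy().sum() == 3  # GP2, GP3, LSS1 dashed cells


def test_reduced_cells_count_as_present():
    panel = y.load_synthetic_panel()
    assert panel.calls.at["GP2", "ORF08"] == 1
    assert panel.reduced.at["GP2", "ORF08"]
    assert panel.deleted_counts()["GP2"] == 20


# ---------------------------------------------------------------- objective


def test_block_count_examples():
    panel = make_panel({"m0": [1, 1, 1, 1, 1]})
    assert mp.count_deletion_blocks(panel.markers, panel) == 0
    panel = make_panel({"m0": [1, 0, 0, 1, 0]})
    assert mp.count_deletion_blocks(panel.markers, panel) == 2


def test_block_count_matches_bruteforce_on_random_matrices():
    rng = np.random.default_rng(0)
    for _ in range(25):
        panel = random_panel(rng, 6, 5)
        order = list(rng.permutation(panel.markers))
        assert mp.count_deletion_blocks(order, panel) == brute_force_blocks(order, panel)


def test_block_count_validates_order():
    panel = make_panel({"m0": [1, 0, 1]})
    with pytest.raises(ValueError, match="permutation"):
        mp.count_deletion_blocks(["M00", "M01"], panel)


def test_objective_invariant_under_reversal():
    rng = np.random.default_rng(1)
    for _ in range(10):
        panel = random_panel(rng, 7, 6)
        order = list(rng.permutation(panel.markers))
        assert mp.count_deletion_blocks(order, panel) == mp.count_deletion_blocks(
            order[::-1], panel
        )


# ---------------------------------------------------------------- exact solver


def test_exact_matches_exhaustive_search():
    rng = np.random.default_rng(2)
    for _ in range(30):
        n = int(rng.integers(2, 8))
        panel = random_panel(rng, n, int(rng.integers(2, 7)))
        res = mp.order_markers_exact(panel)
        best = min(
            mp.count_deletion_blocks(list(p), panel)
            for p in itertools.permutations(panel.markers)
        )
        assert res.objective == best
        assert mp.count_deletion_blocks(res.order, panel) == best
        assert res.exact


def test_exact_single_marker_and_canonical_orientation():
    panel = make_panel({"m0": [0], "m1": [1], "m2": [0]})
    res = mp.order_markers_exact(panel)
    assert res.order == ["M00"] and res.objective == 2
    rng = np.random.default_rng(3)
    p = random_panel(rng, 6, 5)
    res = mp.order_markers_exact(p)
    assert res.order <= res.order[::-1]  # lexicographically canonical direction
    assert res.orientation_arbitrary


def test_exact_refuses_large_panels():
    rng = np.random.default_rng(4)
    panel = random_panel(rng, 12, 5)
    with pytest.raises(ValueError, match="heuristic"):
        mp.order_markers_exact(panel, max_markers=10)


def test_contiguous_single_deletions_reach_one_block_per_mutant():
    true = [f"M{j:02d}" for j in range(8)]
    rows, rng = {}, np.random.default_rng(5)
    for i in range(6):
        a = int(rng.integers(0, 7))
        b = int(rng.integers(a + 1, 9))
        r = [1] * 8
        for k in range(a, min(b, 8)):
            r[k] = 0
        rows[f"m{i}"] = r
    df = pd.DataFrame.from_dict(rows, orient="index", columns=true)
    shuffled = df[list(rng.permutation(true))]
    panel = mp.DeletionPanel(
        calls=shuffled, phenotypes=pd.Series({m: "x" for m in rows})
    )
    res = mp.order_markers_exact(panel)
    n_deleted = int((panel.calls == 0).any(axis=1).sum())
    assert res.objective == n_deleted


def test_adding_all_present_mutant_never_changes_objective():
    rng = np.random.default_rng(6)
    panel = random_panel(rng, 6, 5)
    base = mp.order_markers_exact(panel).objective
    calls = pd.concat(
        [panel.calls, pd.DataFrame([[1] * 6], index=["extra"], columns=panel.markers)]
    )
    phen = pd.concat([panel.phenotypes, pd.Series({"extra": "x"})])
    augmented = mp.DeletionPanel(calls=calls, phenotypes=phen)
    assert mp.order_markers_exact(augmented).objective == base


# ---------------------------------------------------------------- heuristic


def test_heuristic_bounded_below_by_exact_and_deterministic():
    rng = np.random.default_rng(7)
    for trial in range(10):
        panel = random_panel(rng, 7, 6)
        exact = mp.order_markers_exact(panel)
        h1 = mp.order_markers_heuristic(panel, seed=trial)
        h2 = mp.order_markers_heuristic(panel, seed=trial)
        assert h1.order == h2.order and h1.objective == h2.objective
        assert h1.objective >= exact.objective


def test_heuristic_recovers_saturated_staircase_order():
    panel, true = staircase_panel(20)
    res = mp.order_markers_heuristic(panel, seed=0)
    assert res.objective == 19  # one block per mutant
    assert res.order in (true, true[::-1])


# ---------------------------------------------------------------- localization


def test_localize_single_mutant_interval():
    rows = {"e0": [1] * 4 + [0] * 4 + [1] * 4}
    panel = make_panel(rows, {"e0": "ESS"})
    fi = mp.localize_factor(panel, panel.markers, "ESS")
    assert fi.factor == "SPF"
    assert fi.contained_markers == panel.markers[4:8]
    assert fi.left_flank == panel.markers[3]
    assert fi.right_flank == panel.markers[7 + 1]
    assert fi.supporting_mutants == ["e0"]


def test_localize_reports_no_deletion_mutants_as_unexplained():
    rows = {"g0": [0, 0, 1, 1], "g1": [1] * 4}
    panel = make_panel(rows, {"g0": "hermaphrodite", "g1": "hermaphrodite"})
    fi = mp.localize_factor(panel, panel.markers, "hermaphrodite")
    assert fi.factor == "GSF"
    assert fi.unexplained_mutants == ["g1"]
    assert fi.contained_markers == ["M00", "M01"]
    assert fi.left_flank is None and fi.right_flank == "M02"


def test_localize_empty_intersection_raises():
    rows = {"e0": [0, 0, 1, 1], "e1": [1, 1, 0, 0]}
    panel = make_panel(rows, {"e0": "ESS", "e1": "ESS"})
    with pytest.raises(mp.IncompatiblePanelError, match="no marker"):
        mp.localize_factor(panel, panel.markers, "ESS")


def test_localize_composite_phenotypes_join_their_class():
    rows = {"a": [1, 0, 0, 1], "b": [0, 0, 0, 1]}
    panel = make_panel(rows, {"a": "ESS", "b": "hermaphrodite+ESS"})
    fi = mp.localize_factor(panel, panel.markers, "ESS")
    assert set(fi.supporting_mutants) == {"a", "b"}
    assert fi.contained_markers == ["M01", "M02"]


# ---------------------------------------------------------------- genotyping


def test_genotype_by_position_overlap_semantics(small_genome):
    loci = {"A": (1_000, 1_400), "B": (9_000, 9_400), "C": (20_000, 20_400)}
    mutants = [
        y.MutantGenome(name="m0", base=small_genome, deletions={}, phenotype="WT_male"),
        y.MutantGenome(
            name="m1", base=small_genome,
            deletions={"chrY": [(8_000, 21_000)]}, phenotype="x",
        ),
        y.MutantGenome(
            name="m2", base=small_genome,
            deletions={"chrY": [(1_399, 1_500)]}, phenotype="x",
        ),
    ]
    panel = y.genotype_by_position(loci, mutants)
    assert panel.calls.loc["m0"].tolist() == [1, 1, 1]
    assert panel.calls.loc["m1"].tolist() == [1, 0, 0]
    assert panel.calls.loc["m2"].tolist() == [0, 1, 1]  # 1-nt overlap still hits


# ---------------------------------------------------------------- model API


def test_model_fit_summary_and_localize_on_fixture():
    panel = y.load_synthetic_panel()
    res = y.DeletionMapping(panel).fit(method="heuristic", seed=1)
    n_deleted = int((panel.calls == 0).any(axis=1).sum())
    assert res.objective == n_deleted == 14  # one block per deleted mutant
    text = res.summary()
    assert "orientation: arbitrary" in text
    assert "GP1" in text and "SmicSy6" in text

    spf = res.localize("ESS")
    assert {"ScQ14", "SmicSy1", "SmicSy5", "SmicSy6"} <= set(spf.contained_markers)
    mff = res.localize("LSS")
    assert set(mff.contained_markers) == {"SmicSy3", "SmicSy4"}
    gsf = res.localize("hermaphrodite_complete")
    assert gsf.contained_markers == ["MK17"]
    assert gsf.unexplained_mutants == ["R025"]


def test_breakpoint_objective_option():
    panel, true = staircase_panel(10)
    res = y.DeletionMapping(panel, objective="breakpoints").fit(seed=0)
    # interior mutants contribute two call changes, the two edge mutants one
    assert res.objective == 2 * 7 + 2
    assert res.order in (true, true[::-1])
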