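"""Shared test utilities: independent oracles and panel constructors."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from ydelmap.mapping import DeletionPanel


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def random_panel(
    rng: np.random.Generator, n_markers: int, n_mutants: int, p_zero: float = 0.3
) -> DeletionPanel:
    calls = (rng.random((n_mutants, n_markers)) > p_zero).astype(int)
    df = pd.DataFrame(
        calls,
        index=[f"m{i}" for i in range(n_mutants)],
        columns=[f"M{j:02d}" for j in range(n_markers)],
    )
    return DeletionPanel(
        calls=df, phenotypes=pd.Series({f"m{i}": "x" for i in range(n_mutants)})
    )


def brute_force_blocks(order: list[str], panel: DeletionPanel) -> int:
    """Independent run-counting oracle: literal scan of each row string."""
    total = 0
    for mut in panel.mutants:
        row = "".join(str(int(panel.calls.at[mut, mk])) for mk in order)
        total += len([r for r in re.split("1+", row) if r])
    return total


def scan_tracts_regex(sequence: str, unit: str, min_copies: int = 2):
    """Independent maximal-run scanner for (unit)^n, n >= min_copies."""
    pattern = re.compile(f"(?:{unit}){{{min_copies},}}")
    return [(m.start(), (m.end() - m.start()) // 3) for m in pattern.finditer(sequence)]


def staircase_panel(n_markers: int, shuffle_seed: int = 5):
    """Breakpoint-saturated consecutive-ones panel: mutant i deletes markers
    {i, i+1}, so every adjacent marker pair is separated by a breakpoint and
    the true order is recoverable up to reversal."""
    true = [f"MK{k:02d}" for k in range(n_markers)]
    rows = {}
    for i in range(n_markers - 1):
        r = [1] * n_markers
        r[i] = r[i + 1] = 0
        rows[f"m{i}"] = r
    df = pd.DataFrame.from_dict(rows, orient="index", columns=true)
    perm = np.random.default_rng(shuffle_seed).permutation(true).tolist()
    panel = DeletionPanel(
        calls=df[perm], phenotypes=pd.Series({k: "x" for k in rows})
    )
    return panel, true
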