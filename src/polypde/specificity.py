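"""Consensus polyp-specificity calls and Venn-style summaries.

A transcript is *polyp-specific* for polyp X (direction up) when, under
BOTH engines, it is significantly X-higher (p_adj < alpha) in BOTH
pairwise comparisons involving X and not significant in the third
comparison; "down" mirrors with X-lower signs. Transcripts significant in
all three comparisons receive no call (they would not fit a three-way
specificity Venn) and are counted separately in the result metadata.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de_core import ENGINES
from .tables import POLYP_TYPES

#: The three pairwise polyp comparisons, first-named condition = positive log2FC.
STANDARD_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("dactylozooid", "gastrozooid"),
    ("dactylozooid", "gonozooid"),
    ("gastrozooid", "gonozooid"),
)


def comparison_label(comparison: tuple[str, str]) -> str:
    return f"{comparison[0]}_vs_{comparison[1]}"


def _flags_and_signs(
    de_tables: Mapping[tuple[tuple[str, str], str], pd.DataFrame],
    alpha: float,
) -> tuple[pd.Index, dict, dict]:
    keys_needed = [(c, e) for c in STANDARD_COMPARISONS for e in ENGINES]
    missing = [k for k in keys_needed if k not in de_tables]
    if missing:
        raise ValueError(f"missing DE tables for: {missing}")
    universe = None
    sig: dict[tuple, pd.Series] = {}
    sign: dict[tuple, pd.Series] = {}
    for key in keys_needed:
        table = de_tables[key]
        idx = table.index
        if universe is None:
            universe = idx
        elif not universe.equals(idx):
            if set(universe) != set(idx):
                raise ValueError(
                    "DE tables cover different transcript universes; reindex "
                    "them to a common template pool first"
                )
            table = table.reindex(universe)
        tested = table["tested"].eq(True)
        padj = table["p_adj"]
        sig[key] = (padj < alpha).fillna(False) & tested
        sign[key] = np.sign(table["log2_fold_change"]).fillna(0.0)
    return universe, sig, sign


def call_polyp_specific(
    de_tables: Mapping[tuple[tuple[str, str], str], pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Consensus calls from the six (comparison x engine) DE tables.

    ``de_tables`` is keyed by ``(comparison_tuple, engine)`` covering
    :data:`STANDARD_COMPARISONS` x both engines over one transcript
    universe. Returns a DataFrame indexed by transcript with columns
    ``polyp`` ('none' when uncalled), ``direction`` and the twelve
    provenance columns (significance flag and log2FC sign per table).
    ``result.attrs['n_significant_all_three']`` counts transcripts
    significant in all three comparisons under both engines.
    """
    universe, sig, sign = _flags_and_signs(de_tables, alpha)
    n = len(universe)

    calls_polyp = np.array(["none"] * n, dtype=object)
    calls_dir = np.array([""] * n, dtype=object)

    for polyp in POLYP_TYPES:
        involving = [c for c in STANDARD_COMPARISONS if polyp in c]
        third = [c for c in STANDARD_COMPARISONS if polyp not in c][0]
        for direction, want in (("up", 1.0), ("down", -1.0)):
            mask = np.ones(n, dtype=bool)
            for comp in involving:
                # sign meaning "polyp higher": + if polyp is first-named
                orientation = 1.0 if comp[0] == polyp else -1.0
                for engine in ENGINES:
                    key = (comp, engine)
                    mask &= sig[key].to_numpy()
                    mask &= sign[key].to_numpy() == want * orientation
            for engine in ENGINES:
                mask &= ~sig[(third, engine)].to_numpy()
            calls_polyp[mask] = polyp
            calls_dir[mask] = direction

    result = pd.DataFrame({"polyp": calls_polyp, "direction": calls_dir}, index=universe)
    for comp in STANDARD_COMPARISONS:
        for engine in ENGINES:
            key = (comp, engine)
            tag = f"{comparison_label(comp)}.{engine}"
            result[f"sig.{tag}"] = sig[key].to_numpy()
            result[f"sign.{tag}"] = sign[key].to_numpy()

    all_three = np.ones(n, dtype=bool)
    for comp in STANDARD_COMPARISONS:
        for engine in ENGINES:
            all_three &= sig[(comp, engine)].to_numpy()
    result.attrs["n_significant_all_three"] = int(all_three.sum())
    result.attrs["alpha"] = alpha
    return result


def summarize_venn(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-polyp up/down counts plus the Venn intersection convention.

    The intersection of the two circles for polyps X and Y is the number
    of transcripts down-regulated in the excluded polyp Z (down in Z means
    equivocally up in both X and Y).
    """
    rows = []
    for polyp in POLYP_TYPES:
        mine = calls["polyp"] == polyp
        rows.append(
            {
                "polyp": polyp,
                "n_up": int((mine & (calls["direction"] == "up")).sum()),
                "n_down": int((mine & (calls["direction"] == "down")).sum()),
            }
        )
    summary = pd.DataFrame(rows)
    down = dict(zip(summary["polyp"], summary["n_down"]))
    inter = []
    for excluded in POLYP_TYPES:
        pair = tuple(p for p in POLYP_TYPES if p != excluded)
        inter.append(
            {
                "intersection": f"{pair[0]}&{pair[1]}",
                "excluded_polyp": excluded,
                "count": down[excluded],
            }
        )
    summary.attrs["intersections"] = pd.DataFrame(inter)
    return summary
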