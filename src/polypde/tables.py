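"""Shared tabular containers and TSV round-trip helpers.

The pipeline's central objects are plain pandas DataFrames with fixed
conventions:

* **count table** — non-negative integer matrix, index ``transcript_id``,
  one column per ``library_id``.
* **library design** — columns ``library_id``, ``polyp``
  (gastrozooid / gonozooid / dactylozooid) and ``sex``
  (male / female / na); sex is recorded only for gonozooid libraries.
* **DE table** — per-transcript test results (``base_mean``,
  ``log2_fold_change``, ``p_value``, ``p_adj``, ``tested``) for one
  comparison under one engine.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

POLYP_TYPES = ("gastrozooid", "gonozooid", "dactylozooid")
SEXES = ("male", "female", "na")


def make_design(records: Iterable[Sequence[str]]) -> pd.DataFrame:
    """Build and validate a library design from (library_id, polyp, sex) rows."""
    design = pd.DataFrame(list(records), columns=["library_id", "polyp", "sex"])
    validate_design(design)
    return design


def validate_design(design: pd.DataFrame) -> None:
    required = {"library_id", "polyp", "sex"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["library_id"].duplicated().any():
        dup = design.loc[design["library_id"].duplicated(), "library_id"].iloc[0]
        raise ValueError(f"duplicate library_id in design: {dup!r}")
    bad_polyp = set(design["polyp"]) - set(POLYP_TYPES)
    if bad_polyp:
        raise ValueError(f"unknown polyp type(s): {sorted(bad_polyp)}")
    bad_sex = set(design["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex label(s): {sorted(bad_sex)}")
    # sex is meaningful exactly for gonozooid libraries
    gono = design["polyp"] == "gonozooid"
    if (design.loc[gono, "sex"] == "na").any():
        raise ValueError("gonozooid libraries must carry sex = male or female")
    if (design.loc[~gono, "sex"] != "na").any():
        raise ValueError("non-gonozooid libraries must have sex = na")


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate transcript_id in count table")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate library_id in count table")
    values = counts.to_numpy()
    if values.size and (values < 0).any():
        raise ValueError("count table contains negative entries")
    if values.size and not np.allclose(values, np.round(values)):
        raise ValueError("count table contains non-integral entries")


def check_design_matches_counts(design: pd.DataFrame, counts: pd.DataFrame) -> None:
    missing = [lib for lib in design["library_id"] if lib not in counts.columns]
    if missing:
        raise ValueError(f"libraries in design absent from count table: {missing}")


def libraries_for(
    design: pd.DataFrame, polyp: str | None = None, sex: str | None = None
) -> list[str]:
    """Library ids matching a polyp type and/or sex label, in design order."""
    mask = pd.Series(True, index=design.index)
    if polyp is not None:
        mask &= design["polyp"] == polyp
    if sex is not None:
        mask &= design["sex"] == sex
    return design.loc[mask, "library_id"].tolist()


def resolve_condition(design: pd.DataFrame, name: str) -> list[str]:
    """Map a condition name to its member libraries.

    Accepts a polyp type (all its libraries) or ``male`` / ``female``
    (gonozooid libraries of that sex).
    """
    if name in POLYP_TYPES:
        libs = libraries_for(design, polyp=name)
    elif name in ("male", "female"):
        libs = libraries_for(design, polyp="gonozooid", sex=name)
    else:
        raise ValueError(
            f"unknown condition {name!r}; expected one of {POLYP_TYPES + ('male', 'female')}"
        )
    if not libs:
        raise ValueError(f"condition {name!r} has no libraries in this design")
    return libs


# ---------------------------------------------------------------------------
# TSV round trips (first column transcript_id for matrices)
# ---------------------------------------------------------------------------

FLOAT_FORMAT = "%.10g"


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="transcript_id")


def read_counts_tsv(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col="transcript_id")
    validate_counts(counts)
    return counts


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    validate_design(design)
    return design


def write_table_tsv(table: pd.DataFrame, path, index_label: str | None = "transcript_id") -> None:
    table.to_csv(path, sep="\t", index=index_label is not None,
                 index_label=index_label, float_format=FLOAT_FORMAT)


def read_table_tsv(path, index_col: str | None = "transcript_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
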