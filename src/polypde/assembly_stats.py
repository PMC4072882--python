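"""Transcript-catalog length statistics: minimum-length filter, N50, histogram.

The catalog is a DataFrame with columns ``transcript_id`` and ``length``
(bp), read either from FASTA (via Biopython) or from a two-column TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO


def read_catalog_fasta(path) -> pd.DataFrame:
    """Transcript lengths from FASTA; id is the first whitespace token."""
    rows = [(rec.id, len(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    catalog = pd.DataFrame(rows, columns=["transcript_id", "length"])
    _validate(catalog)
    return catalog


def read_catalog_tsv(path) -> pd.DataFrame:
    catalog = pd.read_csv(path, sep="\t")
    if list(catalog.columns[:2]) != ["transcript_id", "length"]:
        catalog.columns = ["transcript_id", "length", *catalog.columns[2:]]
    catalog = catalog[["transcript_id", "length"]]
    _validate(catalog)
    return catalog


def _validate(catalog: pd.DataFrame) -> None:
    if catalog["transcript_id"].duplicated().any():
        raise ValueError("duplicate transcript_id in catalog")
    if len(catalog) and (catalog["length"] < 1).any():
        raise ValueError("transcript lengths must be >= 1 bp")


def filter_min_length(catalog: pd.DataFrame, min_bp: int = 200) -> pd.DataFrame:
    """Retain transcripts of length >= ``min_bp`` (inclusive), order preserved."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return catalog.loc[catalog["length"] >= min_bp].reset_index(drop=True)


def n50(catalog: pd.DataFrame | np.ndarray | list) -> int:
    """Largest length L such that transcripts >= L cover half the assembly.

    Standard assembly-stats convention: sort lengths descending and return
    the length at which the cumulative sum first reaches 50% of total bases.
    """
    if isinstance(catalog, pd.DataFrame):
        lengths = catalog["length"].to_numpy()
    else:
        lengths = np.asarray(catalog)
    if lengths.size == 0:
        raise ValueError("N50 undefined for an empty catalog")
    desc = np.sort(lengths)[::-1]
    cumulative = np.cumsum(desc)
    idx = int(np.searchsorted(cumulative, cumulative[-1] / 2.0))
    return int(desc[idx])


def length_histogram(
    catalog: pd.DataFrame, bin_width: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Half-open bins [lo, lo + width); counts sum to the catalog size."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    lengths = catalog["length"].to_numpy()
    if lengths.size == 0:
        return np.array([0, bin_width]), np.array([0])
    lo = (lengths.min() // bin_width) * bin_width
    hi = (lengths.max() // bin_width + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    # np.histogram closes the last bin; our final edge exceeds max so every
    # data bin is effectively half-open
    return edges, counts


def summary(catalog: pd.DataFrame, min_bp: int = 200) -> pd.DataFrame:
    """One-row summary before/after the minimum-length filter."""
    kept = filter_min_length(catalog, min_bp)
    rows = []
    for label, cat in (("all", catalog), (f">={min_bp}bp", kept)):
        rows.append(
            {
                "subset": label,
                "n_transcripts": len(cat),
                "total_bp": int(cat["length"].sum()),
                "n50_bp": n50(cat) if len(cat) else 0,
                "mean_bp": float(cat["length"].mean()) if len(cat) else 0.0,
                "max_bp": int(cat["length"].max()) if len(cat) else 0,
            }
        )
    return pd.DataFrame(rows)
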