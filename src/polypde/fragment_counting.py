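"""Pair-aware fragment counting from SAM alignments.

A fragment (template) contributes one count to transcript *t* iff both of
its mates have primary alignments and both of those alignments reference
*t*. Everything else — unmapped mates, mates split across transcripts,
secondary/supplementary records, single-end records — contributes nothing.
This is the counting contract the rest of the pipeline assumes for
paired-end libraries mapped against a transcriptome.

Only three SAM fields are consumed (QNAME, FLAG, RNAME); the reader
reports malformed lines by line number. Input need not be name-sorted: an
index by template name is built while streaming.
"""

from __future__ import annotations

import io
import os
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


class SamParseError(ValueError):
    """Raised for unparseable SAM input; message names the offending line."""


class PairingError(ValueError):
    """Raised when a template carries more than two primary paired records."""


def _open_lines(sam) -> Iterable[str]:
    if isinstance(sam, (str, os.PathLike)):
        text = str(sam)
        if "\n" in text:  # raw SAM text rather than a path
            return io.StringIO(text)
        return open(sam, "r")
    return sam  # file-like or iterable of lines


def iter_sam_records(sam) -> Iterator[tuple[int, str, int, str]]:
    """Yield (line_number, qname, flag, rname) for each alignment line."""
    lines = _open_lines(sam)
    try:
        for lineno, line in enumerate(lines, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise SamParseError(
                    f"SAM line {lineno}: expected >= 11 tab-separated fields, "
                    f"got {len(fields)}"
                )
            qname = fields[0]
            try:
                flag = int(fields[1])
            except ValueError:
                raise SamParseError(
                    f"SAM line {lineno}: FLAG field {fields[1]!r} is not an integer"
                ) from None
            if flag < 0:
                raise SamParseError(f"SAM line {lineno}: negative FLAG {flag}")
            yield lineno, qname, flag, fields[2]
    finally:
        if hasattr(lines, "close"):
            lines.close()


def sam_references(sam) -> list[str]:
    """Reference names from @SQ header lines, in order."""
    refs = []
    lines = _open_lines(sam)
    try:
        for line in lines:
            if not line.startswith("@"):
                break
            if line.startswith("@SQ"):
                for field in line.rstrip("\n").split("\t")[1:]:
                    if field.startswith("SN:"):
                        refs.append(field[3:])
    finally:
        if hasattr(lines, "close"):
            lines.close()
    return refs


def count_fragments(sam, transcript_ids: Sequence[str]) -> pd.Series:
    """Count same-transcript concordant fragments per transcript.

    Returns an integer Series indexed by ``transcript_ids`` (order
    preserved); transcripts absent from the alignments get 0.
    """
    ids = list(transcript_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("transcript_ids must be unique")

    # template name -> list of (is_first_mate, mapped, rname) primary records
    templates: dict[str, list[tuple[bool, bool, str]]] = {}
    for lineno, qname, flag, rname in iter_sam_records(sam):
        if not flag & FLAG_PAIRED:
            continue  # single-end records are outside the contract
        if flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
            continue  # primary alignments only
        recs = templates.setdefault(qname, [])
        recs.append((bool(flag & FLAG_FIRST), not flag & FLAG_UNMAPPED, rname))
        if len(recs) > 2:
            raise PairingError(
                f"template {qname!r} has more than two primary paired records "
                f"(third seen at SAM line {lineno})"
            )

    counts = dict.fromkeys(ids, 0)
    for qname, recs in templates.items():
        if len(recs) != 2:
            continue
        (first_a, mapped_a, ref_a), (first_b, mapped_b, ref_b) = recs
        if first_a == first_b:
            continue  # not a first/second mate pair
        if not (mapped_a and mapped_b):
            continue
        if ref_a != ref_b or ref_a == "*":
            continue
        if ref_a in counts:
            counts[ref_a] += 1

    return pd.Series([counts[t] for t in ids], index=pd.Index(ids, name="transcript_id"),
                     dtype=int)


def build_count_table(
    sam_by_library: Mapping[str, object], transcript_ids: Sequence[str]
) -> pd.DataFrame:
    """One fragment-count column per library; column order follows the mapping.

    ``sam_by_library`` maps library_id to a SAM path (or text / file-like).
    """
    columns = {}
    for library_id, sam in sam_by_library.items():
        if isinstance(sam, (str, os.PathLike)) and "\n" not in str(sam):
            if not Path(sam).exists():
                raise FileNotFoundError(
                    f"SAM file for library {library_id!r} not found: {sam}"
                )
        columns[library_id] = count_fragments(sam, transcript_ids)
    table = pd.DataFrame(columns)
    table.index.name = "transcript_id"
    return table
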