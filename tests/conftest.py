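"""Shared fixtures: designs, small simulations, and a random-SAM generator."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polypde.synthetic_data import SimulationParams, default_design, simulate_counts


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def small_sim(design):
    """A modest default-condition simulation shared across read-only tests."""
    params = SimulationParams(n_transcripts=1500, seed=77)
    counts, truth = simulate_counts(params, design)
    return params, counts, truth


def random_sam(rng: np.random.Generator, n_templates: int = 50):
    """A randomized SAM document plus the per-template primary-record list.

    Returns ``(sam_text, refs, records)`` where records maps template name
    to its primary paired records as (is_first, mapped, rname) tuples —
    enough for a literal brute-force re-count.
    """
    refs = [f"T{i}" for i in range(rng.integers(2, 8))]
    header = ["@HD\tVN:1.6"] + [f"@SQ\tSN:{r}\tLN:500" for r in refs]
    body = []
    records: dict[str, list[tuple[bool, bool, str]]] = {}

    def line(qname, flag, rname):
        pos = "1" if rname != "*" else "0"
        return "\t".join([qname, str(flag), rname, pos, "60", "5M" if rname != "*" else "*",
                          "*", "0", "0", "AAAAA", "IIIII"])

    for t in range(n_templates):
        qname = f"tpl{t}"
        kind = rng.integers(0, 6)
        recs = []
        if kind == 0:  # concordant pair
            ref = refs[rng.integers(len(refs))]
            recs = [(True, True, ref), (False, True, ref)]
        elif kind == 1:  # split pair
            i, j = rng.choice(len(refs), size=2, replace=False)
            recs = [(True, True, refs[i]), (False, True, refs[j])]
        elif kind == 2:  # mate unmapped
            ref = refs[rng.integers(len(refs))]
            recs = [(True, True, ref), (False, False, "*")]
        elif kind == 3:  # both unmapped
            recs = [(True, False, "*"), (False, False, "*")]
        elif kind == 4:  # lone first mate
            ref = refs[rng.integers(len(refs))]
            recs = [(True, True, ref)]
        else:  # concordant + secondary noise
            ref = refs[rng.integers(len(refs))]
            recs = [(True, True, ref), (False, True, ref)]
            sec_ref = refs[rng.integers(len(refs))]
            body.append(line(qname, (0x1 | 0x40 | 0x100), sec_ref))
        for is_first, mapped, rname in recs:
            flag = 0x1 | (0x40 if is_first else 0x80) | (0 if mapped else 0x4)
            body.append(line(qname, flag, rname))
        records[qname] = recs

    order = rng.permutation(len(body))  # not name-sorted on purpose
    sam = "\n".join(header + [body[i] for i in order]) + "\n"
    return sam, refs, records


def brute_force_counts(refs, records) -> pd.Series:
    """Literal restatement of the counting rule, independent of the parser."""
    out = dict.fromkeys(refs, 0)
    for recs in records.values():
        if len(recs) != 2:
            continue
        firsts = [r for r in recs if r[0]]
        seconds = [r for r in recs if not r[0]]
        if len(firsts) != 1 or len(seconds) != 1:
            continue
        (_, map1, ref1), (_, map2, ref2) = firsts[0], seconds[0]
        if map1 and map2 and ref1 == ref2 and ref1 in out:
            out[ref1] += 1
    return pd.Series(out)
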