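"""Synthetic count matrices and SAM fixtures with known ground truth.

Emulates the statistical structure assumed by the downstream analysis: a
colony of *Hydractinia*-style polymorphic polyps sampled as 12 RNA-seq
libraries (4 gastrozooid, 4 dactylozooid, 2 male + 2 female gonozooid),
negative-binomial counts with library-specific depths and per-transcript
dispersions, and designated effect classes:

``null``
    no expression difference anywhere.
``gast_up/down``, ``dact_up/down``, ``gono_up/down``
    somatic effect in all libraries of one polyp type.
``male_gametic`` / ``female_gametic``
    heterogametic expression — modulates only the matching-sex gonozooid
    libraries (gametogenesis, not polyp identity).
``maternal_somatic``
    maternal transcripts: female-up gametic shift *and* a genuine
    gonozooid-somatic effect. This is the class the adjustment workflow's
    "red branch" exists to rescue.

Counts for transcript *i* in library *j* are drawn NB with mean
``depth_j * q_i * 2**offset_ij`` and variance ``mu + alpha_i * mu**2``,
where the log2 offset encodes the transcript's effect class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import make_design

EFFECT_CLASSES = (
    "null",
    "gast_up",
    "gast_down",
    "dact_up",
    "dact_down",
    "gono_up",
    "gono_down",
    "male_gametic",
    "female_gametic",
    "maternal_somatic",
)

DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "null": 0.80,
    "gast_up": 0.02,
    "gast_down": 0.02,
    "dact_up": 0.02,
    "dact_down": 0.02,
    "gono_up": 0.02,
    "gono_down": 0.02,
    "male_gametic": 0.03,
    "female_gametic": 0.03,
    "maternal_somatic": 0.02,
}


def default_design() -> pd.DataFrame:
    """The study design: 12 libraries, 4 per polyp type, gonozooids sexed.

    Go1/Go2 are female and Go3/Go4 male, matching the usual labelling of
    the two reproductive-polyp sexes.
    """
    rows = (
        [(f"Ga{i}", "gastrozooid", "na") for i in range(1, 5)]
        + [("Go1", "gonozooid", "female"), ("Go2", "gonozooid", "female"),
           ("Go3", "gonozooid", "male"), ("Go4", "gonozooid", "male")]
        + [(f"Da{i}", "dactylozooid", "na") for i in range(1, 5)]
    )
    return make_design(rows)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the count simulator.

    ``log2_effect`` is the somatic polyp-effect magnitude (log2 units);
    ``gametic_log2_effect`` the male/female gametic shift;
    ``maternal_gametic_log2_effect`` the female-up component carried by
    maternal transcripts (fixed at +2 by default). Baseline means are
    log2-uniform over ``baseline_log2_range`` and dispersions log-normal
    with the given log-mean/log-sd (``dispersion_log_mean=None`` gives
    Poisson counts). ``depth_factors=None`` draws per-library depths
    log2-uniform over ``depth_log2_range``.
    """

    n_transcripts: int = 5000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    log2_effect: float = 3.0
    gametic_log2_effect: float = 4.0
    maternal_gametic_log2_effect: float = 2.0
    baseline_log2_range: tuple[float, float] = (2.0, 12.0)
    dispersion_log_mean: float | None = math.log(0.1)
    dispersion_log_sd: float = 0.8
    depth_factors: tuple[float, ...] | None = None
    depth_log2_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        props = dict(self.class_proportions)
        unknown = set(props) - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect class(es): {sorted(unknown)}")
        vals = np.array([props.get(c, 0.0) for c in EFFECT_CLASSES], dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("class proportions must be finite and non-negative")
        if abs(vals.sum() - 1.0) > 1e-8:
            raise ValueError(f"class proportions must sum to 1 (got {vals.sum()})")
        for name in ("log2_effect", "gametic_log2_effect", "maternal_gametic_log2_effect"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        lo, hi = self.baseline_log2_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError("baseline_log2_range must be a finite interval")
        if self.dispersion_log_mean is not None and math.isnan(self.dispersion_log_mean):
            raise ValueError("dispersion_log_mean must not be NaN")
        if not (np.isfinite(self.dispersion_log_sd) and self.dispersion_log_sd >= 0):
            raise ValueError("dispersion_log_sd must be finite and >= 0")
        if self.depth_factors is not None:
            df = np.asarray(self.depth_factors, dtype=float)
            if np.any(~np.isfinite(df)) or np.any(df <= 0):
                raise ValueError("depth_factors must be positive and finite")

    def class_probabilities(self) -> np.ndarray:
        props = dict(self.class_proportions)
        return np.array([props.get(c, 0.0) for c in EFFECT_CLASSES], dtype=float)


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    # one root seed, per-stage derived streams: adding transcripts extends a
    # stage's draw sequence without reshuffling other stages
    root = np.random.SeedSequence(seed)
    names = ("classes", "baseline", "dispersion", "depth", "counts")
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _log2_offsets(params: SimulationParams, design: pd.DataFrame) -> np.ndarray:
    """Per-(effect class, library) log2 mean offsets."""
    polyp = design["polyp"].to_numpy()
    sex = design["sex"].to_numpy()
    gast = (polyp == "gastrozooid").astype(float)
    dact = (polyp == "dactylozooid").astype(float)
    gono = (polyp == "gonozooid").astype(float)
    gono_m = ((polyp == "gonozooid") & (sex == "male")).astype(float)
    gono_f = ((polyp == "gonozooid") & (sex == "female")).astype(float)

    L = params.log2_effect
    G = params.gametic_log2_effect
    M = params.maternal_gametic_log2_effect
    rows = {
        "null": np.zeros(len(design)),
        "gast_up": L * gast,
        "gast_down": -L * gast,
        "dact_up": L * dact,
        "dact_down": -L * dact,
        "gono_up": L * gono,
        "gono_down": -L * gono,
        "male_gametic": G * gono_m,
        "female_gametic": G * gono_f,
        # female-up gametic shift AND a somatic gonozooid effect
        "maternal_somatic": M * gono_f + L * gono,
    }
    return np.stack([rows[c] for c in EFFECT_CLASSES])


def simulate_counts(
    params: SimulationParams, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a (count table, truth table) pair.

    Deterministic: identical ``(params, design)`` — including
    ``params.seed`` — reproduce the same matrices bit for bit.
    """
    params.validate()
    if len(design) == 0:
        raise ValueError("design must contain at least one library")
    rngs = _stage_rngs(params.seed)
    n = params.n_transcripts
    m = len(design)

    probs = params.class_probabilities()
    class_idx = rngs["classes"].choice(len(EFFECT_CLASSES), size=n, p=probs)

    lo, hi = params.baseline_log2_range
    q = np.exp2(rngs["baseline"].uniform(lo, hi, size=n))

    if params.dispersion_log_mean is None:
        alpha = np.zeros(n)
    else:
        alpha = np.exp(
            rngs["dispersion"].normal(
                params.dispersion_log_mean, params.dispersion_log_sd, size=n
            )
        )

    if params.depth_factors is not None:
        depth = np.asarray(params.depth_factors, dtype=float)
        if len(depth) != m:
            raise ValueError(
                f"depth_factors has {len(depth)} entries for {m} libraries"
            )
    else:
        depth = np.exp2(rngs["depth"].uniform(*params.depth_log2_range, size=m))

    offsets = _log2_offsets(params, design)  # classes x libraries
    mu = depth[None, :] * q[:, None] * np.exp2(offsets[class_idx])

    counts = np.empty((n, m), dtype=np.int64)
    rng_counts = rngs["counts"]
    for i in range(n):  # row-major so earlier transcripts are stable under growth
        if alpha[i] > 0:
            size = 1.0 / alpha[i]
            p = size / (size + mu[i])
            counts[i] = rng_counts.negative_binomial(size, p)
        else:
            counts[i] = rng_counts.poisson(mu[i])

    transcript_ids = [f"T{i:06d}" for i in range(n)]
    count_table = pd.DataFrame(
        counts, index=pd.Index(transcript_ids, name="transcript_id"),
        columns=design["library_id"].tolist(),
    )

    class_names = np.array(EFFECT_CLASSES)[class_idx]
    signed = np.zeros(n)
    for name, value in (
        ("gast_up", params.log2_effect), ("gast_down", -params.log2_effect),
        ("dact_up", params.log2_effect), ("dact_down", -params.log2_effect),
        ("gono_up", params.log2_effect), ("gono_down", -params.log2_effect),
        ("male_gametic", params.gametic_log2_effect),
        ("female_gametic", params.gametic_log2_effect),
        ("maternal_somatic", params.log2_effect),
    ):
        signed[class_names == name] = value
    truth = pd.DataFrame(
        {
            "effect_class": class_names,
            "log2_effect": signed,
            "true_dispersion": alpha,
            "baseline_mean": q,
        },
        index=count_table.index,
    )
    return count_table, truth


# ---------------------------------------------------------------------------
# SAM fixtures for the fragment-counting contract
# ---------------------------------------------------------------------------

_READ_LEN = 10
_SEQ = "A" * _READ_LEN
_QUAL = "I" * _READ_LEN
_REF_LEN = 1000
_DECOYS = ("NOISE_REF_A", "NOISE_REF_B")


def _sam_line(qname, flag, rname, pos, mapq, cigar, rnext, pnext, tlen) -> str:
    return "\t".join(
        [qname, str(flag), rname, str(pos), str(mapq), cigar,
         rnext, str(pnext), str(tlen), _SEQ, _QUAL]
    )


def simulate_alignments(target_counts: pd.Series | Mapping[str, int], noise: int = 0) -> str:
    """Emit SAM v1 text whose pair-aware fragment counts equal ``target_counts``.

    Per transcript *t*, exactly ``target_counts[t]`` concordant pairs (flags
    99/147, both mates primary-mapped to *t*) are written, plus ``noise``
    distractor templates that must never be counted, cycling through three
    kinds: a pair with one mate unmapped, a pair whose mates map to
    different references, and a template whose only mapped records are
    secondary alignments.
    """
    if not isinstance(target_counts, pd.Series):
        target_counts = pd.Series(dict(target_counts), dtype=int)
    if len(target_counts) and (target_counts < 0).any():
        raise ValueError("target counts must be non-negative")
    if noise < 0:
        raise ValueError("noise must be non-negative")

    refs = [str(t) for t in target_counts.index]
    header = ["@HD\tVN:1.6\tSO:unknown"]
    for ref in refs:
        header.append(f"@SQ\tSN:{ref}\tLN:{_REF_LEN}")
    if noise > 0:
        for decoy in _DECOYS:
            header.append(f"@SQ\tSN:{decoy}\tLN:{_REF_LEN}")

    body: list[str] = []
    for ref in refs:
        for k in range(int(target_counts[ref])):
            qname = f"frag:{ref}:{k}"
            body.append(_sam_line(qname, 99, ref, 1, 60, f"{_READ_LEN}M", "=", 21, 30))
            body.append(_sam_line(qname, 147, ref, 21, 60, f"{_READ_LEN}M", "=", 1, -30))

    noise_refs = (refs + list(_DECOYS)) if noise > 0 else []
    for k in range(noise):
        qname = f"noise:{k}"
        ref_a = noise_refs[k % len(noise_refs)]
        ref_b = noise_refs[(k + 1) % len(noise_refs)]
        kind = k % 3
        if kind == 0:
            # mate 2 unmapped
            body.append(_sam_line(qname, 73, ref_a, 1, 60, f"{_READ_LEN}M", "*", 0, 0))
            body.append(_sam_line(qname, 133, "*", 0, 0, "*", "*", 0, 0))
        elif kind == 1:
            # mates on different references
            body.append(_sam_line(qname, 65, ref_a, 1, 60, f"{_READ_LEN}M", ref_b, 1, 0))
            body.append(_sam_line(qname, 129, ref_b, 1, 60, f"{_READ_LEN}M", ref_a, 1, 0))
        else:
            # primary records unmapped; mapped records are secondary only
            body.append(_sam_line(qname, 77, "*", 0, 0, "*", "*", 0, 0))
            body.append(_sam_line(qname, 141, "*", 0, 0, "*", "*", 0, 0))
            body.append(_sam_line(qname, 99 | 0x100, ref_a, 1, 0, f"{_READ_LEN}M", "=", 21, 30))
            body.append(_sam_line(qname, 147 | 0x100, ref_a, 21, 0, f"{_READ_LEN}M", "=", 1, -30))

    return "\n".join(header + body) + "\n"


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.10g")
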