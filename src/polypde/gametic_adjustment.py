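"""Heterogametic adjustment: screen, partition, and staged cross-polyp DE.

Male and female gonozooids differ morphologically only in the gametes they
carry, so expression differences between them are attributed to
gametogenesis rather than polyp identity and must be removed before
comparing polyp types. The workflow:

1. DE between male and female gonozooid libraries (the *screen*).
2. Partition transcripts at p_adj < alpha into ``male_up`` / ``female_up``
   / ``nonsig``.
3. *Black branch* — cross-polyp DE on the non-significant template pool,
   gonozooid condition represented by all four gonozooid libraries.
   *Red branch* — cross-polyp DE on the female-up pool (putative maternal
   transcripts, which may also matter somatically), gonozooid condition
   represented by the two male libraries only, so the maternal signal
   cannot masquerade as a polyp effect.
   Male-up transcripts are excluded from cross-polyp testing entirely.
4. The two branches, each BH-adjusted within itself, are combined.

Throughout, dispersion is estimated with male and female gonozooids as
separate conditions, which lowers per-transcript dispersion estimates and
raises power when sex effects are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .de_core import DispersionFit, estimate_dispersion, run_de, significant, size_factors
from .tables import libraries_for, resolve_condition

BRANCH_BLACK = "black"
BRANCH_RED = "red"


def pooled_conditions(design: pd.DataFrame) -> dict[str, str]:
    """Dispersion grouping with all gonozooids binned as one condition."""
    return dict(zip(design["library_id"], design["polyp"]))


def split_sex_conditions(design: pd.DataFrame) -> dict[str, str]:
    """Dispersion grouping with male and female gonozooids as separate conditions."""
    labels = {}
    for _, row in design.iterrows():
        if row["polyp"] == "gonozooid":
            labels[row["library_id"]] = f"gonozooid_{row['sex']}"
        else:
            labels[row["library_id"]] = row["polyp"]
    return labels


@dataclass
class GameticPartition:
    """Disjoint transcript sets from the male-vs-female screen."""

    nonsig: frozenset
    male_up: frozenset
    female_up: frozenset
    alpha: float
    engine: str
    screen: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        sets = (self.nonsig, self.male_up, self.female_up)
        total = sum(len(s) for s in sets)
        union = self.nonsig | self.male_up | self.female_up
        if total != len(union):
            raise ValueError("partition sets must be pairwise disjoint")

    def all_transcripts(self) -> frozenset:
        return self.nonsig | self.male_up | self.female_up


def partition_by_sex(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    engine: str = "conservative",
    alpha: float = 0.05,
    dispersion: DispersionFit | None = None,
) -> GameticPartition:
    """Screen male vs female gonozooids and partition every transcript.

    ``male_up`` = significant with positive log2FC (male first-named),
    ``female_up`` = significant with negative log2FC, ``nonsig`` = the
    rest including not-tested transcripts.
    """
    males = libraries_for(design, polyp="gonozooid", sex="male")
    females = libraries_for(design, polyp="gonozooid", sex="female")
    if len(males) < 2 or len(females) < 2:
        raise ValueError(
            "the sex screen needs >= 2 male and >= 2 female gonozooid libraries; "
            f"found {len(males)} male, {len(females)} female"
        )
    screen = run_de(
        counts,
        design,
        ("male", "female"),
        engine,
        dispersion=dispersion,
        dispersion_conditions=split_sex_conditions(design),
    )
    sig = significant(screen, alpha)
    lfc = screen["log2_fold_change"]
    male_up = frozenset(screen.index[sig & (lfc > 0)])
    female_up = frozenset(screen.index[sig & (lfc < 0)])
    nonsig = frozenset(screen.index) - male_up - female_up
    return GameticPartition(
        nonsig=nonsig, male_up=male_up, female_up=female_up,
        alpha=alpha, engine=engine, screen=screen,
    )


def _branch_groups(design: pd.DataFrame, comparison: tuple[str, str], red: bool):
    """Library groups for one branch; red branch restricts gonozooids to males."""
    groups = []
    for name in comparison:
        libs = resolve_condition(design, name)
        if red and name == "gonozooid":
            libs = libraries_for(design, polyp="gonozooid", sex="male")
        groups.append(libs)
    return groups


def run_adjusted(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    partition: GameticPartition,
    comparison: tuple[str, str],
    engine: str = "conservative",
    dispersion: DispersionFit | None = None,
) -> pd.DataFrame:
    """Gametically adjusted cross-polyp DE: black + red branches combined.

    Rows carry a ``branch`` column; the two branches are disjoint by
    construction (black tests the non-significant pool, red the female-up
    pool) and each is BH-adjusted within itself. Male-up transcripts are
    tested in neither branch.
    """
    if engine != partition.engine:
        raise ValueError(
            f"partition was computed with engine {partition.engine!r}, "
            f"adjusted analysis requested with {engine!r}"
        )
    if dispersion is None:
        factors = size_factors(counts)
        dispersion = estimate_dispersion(
            counts, factors, split_sex_conditions(design), engine
        )

    pieces = []
    for branch, pool, red in (
        (BRANCH_BLACK, partition.nonsig, False),
        (BRANCH_RED, partition.female_up, True),
    ):
        pool_ids = [t for t in counts.index if t in pool]
        if not pool_ids:
            continue
        libs_a, libs_b = _branch_groups(design, comparison, red)
        table = run_de(
            counts,
            design,
            comparison,
            engine,
            dispersion=dispersion,
            group_a=libs_a,
            group_b=libs_b,
            transcripts=pool_ids,
        )
        table = table.copy()
        table["branch"] = branch
        pieces.append(table)

    if not pieces:
        raise ValueError("partition leaves no transcripts to test")
    combined = pd.concat(pieces)
    combined = combined.loc[[t for t in counts.index if t in combined.index]]
    combined.attrs["comparison"] = f"{comparison[0]}_vs_{comparison[1]}"
    combined.attrs["engine"] = engine
    combined.attrs["adjustment"] = "per-branch BH; male_up transcripts untested"
    return combined


def run_full(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    comparison: tuple[str, str],
    engine: str = "conservative",
    dispersion: DispersionFit | None = None,
) -> pd.DataFrame:
    """Unadjusted analysis: all transcripts, gonozooid sexes binned together."""
    return run_de(
        counts,
        design,
        comparison,
        engine,
        dispersion=dispersion,
        dispersion_conditions=pooled_conditions(design),
    )
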