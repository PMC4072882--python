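"""End-to-end orchestration: simulate/load -> DE -> adjust -> classify -> diagnose.

`run_pipeline` writes every stage's tables as TSV plus a JSON manifest
(config echo, seed, package versions, per-stage row counts, file hashes).
Identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de_core import ENGINES, estimate_dispersion, significant, size_factors
from .diagnostics import (
    dispersion_mean_data,
    library_distances,
    ma_data,
    mds_2d,
    within_between_ratio,
)
from .gametic_adjustment import (
    partition_by_sex,
    pooled_conditions,
    run_adjusted,
    run_full,
    split_sex_conditions,
)
from .specificity import (
    STANDARD_COMPARISONS,
    call_polyp_specific,
    comparison_label,
    summarize_venn,
)
from .synthetic_data import SimulationParams, default_design, simulate_counts
from .tables import (
    read_counts_tsv,
    read_design_tsv,
    write_counts_tsv,
    write_design_tsv,
    write_table_tsv,
)

logger = logging.getLogger("polypde")


@dataclass
class PipelineConfig:
    """Configuration for a full run.

    Either ``counts_path`` + ``design_path`` point at existing tables, or
    (default) data are simulated with ``sim`` (its seed is overridden by
    ``seed``).
    """

    counts_path: str | None = None
    design_path: str | None = None
    sim: SimulationParams = field(default_factory=SimulationParams)
    alpha: float = 0.05
    engines: tuple[str, ...] = ENGINES
    min_length: int = 200
    output_dir: str = "polypde_out"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        unknown = set(self.engines) - set(ENGINES)
        if unknown:
            raise ValueError(f"unknown engine(s): {sorted(unknown)}")
        if (self.counts_path is None) != (self.design_path is None):
            raise ValueError("counts_path and design_path must be given together")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        sim = SimulationParams(**sim_raw) if not isinstance(sim_raw, SimulationParams) else sim_raw
        engines = tuple(raw.pop("engines", ENGINES))
        cfg = cls(sim=sim, engines=engines, **raw)
        cfg.validate()
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        d["sim"]["class_proportions"] = dict(self.sim.class_proportions)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(out_dir: Path) -> logging.FileHandler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    handler.setFormatter(fmt)
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(fmt)
        logger.addHandler(stream)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    manifest: dict = {
        "package": "polypde",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": config.to_jsonable(),
        "seed": config.seed,
        "stages": {},
        "files": {},
    }
    written: dict[str, Path] = {}

    def emit(name: str, table, index_label="transcript_id"):
        path = out / name
        write_table_tsv(table, path, index_label=index_label)
        written[name] = path

    try:
        # ------------------------------------------------------------ data
        if config.counts_path is not None:
            counts = read_counts_tsv(config.counts_path)
            design = read_design_tsv(config.design_path)
            truth = None
        else:
            design = default_design()
            sim = dataclasses.replace(config.sim, seed=config.seed)
            counts, truth = simulate_counts(sim, design)
        write_design_tsv(design, out / "design.tsv")
        written["design.tsv"] = out / "design.tsv"
        write_counts_tsv(counts, out / "counts.tsv")
        written["counts.tsv"] = out / "counts.tsv"
        if truth is not None:
            emit("truth.tsv", truth)
        manifest["stages"]["input"] = {
            "n_transcripts": int(len(counts)),
            "n_libraries": int(counts.shape[1]),
            "simulated": truth is not None,
        }
        logger.info("input: %d transcripts x %d libraries", *counts.shape)

        factors = size_factors(counts)
        emit("size_factors.tsv", factors.to_frame(), index_label="library_id")

        # ---------------------------------------------- dispersion fits
        fits_split = {}
        fits_pooled = {}
        for engine in config.engines:
            fits_split[engine] = estimate_dispersion(
                counts, factors, split_sex_conditions(design), engine
            )
            fits_pooled[engine] = estimate_dispersion(
                counts, factors, pooled_conditions(design), engine
            )
            for label, fit in (("split", fits_split[engine]), ("pooled", fits_pooled[engine])):
                points, trend = dispersion_mean_data(fit)
                emit(f"dispersion_{label}_{engine}.tsv", points)
                emit(f"dispersion_trend_{label}_{engine}.tsv", trend, index_label=None)
            manifest["stages"][f"dispersion_{engine}"] = {
                "mean_final_alpha_split": float(
                    np.nanmean(fits_split[engine].table["final_alpha"])
                ),
                "mean_final_alpha_pooled": float(
                    np.nanmean(fits_pooled[engine].table["final_alpha"])
                ),
            }

        # ------------------------------------------------------- screen
        partitions = {}
        sex_significant: set[str] = set()
        for engine in config.engines:
            part = partition_by_sex(
                counts, design, engine, config.alpha, dispersion=fits_split[engine]
            )
            partitions[engine] = part
            sex_significant |= set(part.male_up) | set(part.female_up)
            rows = pd.DataFrame(
                {
                    "set": [
                        "male_up" if t in part.male_up
                        else "female_up" if t in part.female_up
                        else "nonsig"
                        for t in counts.index
                    ]
                },
                index=counts.index,
            )
            emit(f"partition_{engine}.tsv", rows)
            emit(f"de_sex_{engine}.tsv", part.screen)
            manifest["stages"][f"partition_{engine}"] = {
                "nonsig": len(part.nonsig),
                "male_up": len(part.male_up),
                "female_up": len(part.female_up),
            }
            logger.info(
                "partition[%s]: %d nonsig / %d male_up / %d female_up",
                engine, len(part.nonsig), len(part.male_up), len(part.female_up),
            )

        # ------------------------------------------------- full + adjusted DE
        adjusted_tables = {}
        for engine in config.engines:
            for comp in STANDARD_COMPARISONS:
                label = comparison_label(comp)
                full = run_full(counts, design, comp, engine, dispersion=fits_pooled[engine])
                emit(f"de_full_{label}_{engine}.tsv", full)
                adj = run_adjusted(
                    counts, design, partitions[engine], comp, engine,
                    dispersion=fits_split[engine],
                )
                emit(f"de_adjusted_{label}_{engine}.tsv", adj)
                adjusted_tables[(comp, engine)] = adj
                manifest["stages"][f"de_{label}_{engine}"] = {
                    "full_significant": int(significant(full, config.alpha).sum()),
                    "adjusted_significant": int(significant(adj, config.alpha).sum()),
                    "adjusted_rows": int(len(adj)),
                }

        # ------------------------------------------------- specificity
        if set(config.engines) == set(ENGINES):
            universe = counts.index
            reindexed = {}
            for key, table in adjusted_tables.items():
                t = table.reindex(universe)
                t["tested"] = t["tested"].eq(True)
                reindexed[key] = t
            calls = call_polyp_specific(reindexed, config.alpha)
            emit("specificity_calls.tsv", calls)
            venn = summarize_venn(calls)
            emit("venn_summary.tsv", venn, index_label=None)
            emit("venn_intersections.tsv", venn.attrs["intersections"], index_label=None)
            manifest["stages"]["specificity"] = {
                "n_called": int((calls["polyp"] != "none").sum()),
                "n_significant_all_three": calls.attrs["n_significant_all_three"],
            }
        else:
            logger.info("specificity skipped: consensus rule needs both engines")
            manifest["stages"]["specificity"] = {"skipped": "needs both engines"}

        # ------------------------------------------------- diagnostics
        dist_full = library_distances(counts, factors)
        emit("distances_full.tsv", dist_full, index_label="library_id")
        emit("embedding_full.tsv", mds_2d(dist_full), index_label="library_id")
        diag = {"within_between_ratio_full": within_between_ratio(dist_full, design)}
        if sex_significant and len(sex_significant) < len(counts):
            dist_adj = library_distances(counts, factors, exclude=sex_significant)
            emit("distances_adjusted.tsv", dist_adj, index_label="library_id")
            emit("embedding_adjusted.tsv", mds_2d(dist_adj), index_label="library_id")
            diag["within_between_ratio_adjusted"] = within_between_ratio(dist_adj, design)
        for engine in config.engines:
            emit(f"ma_sex_{engine}.tsv", ma_data(partitions[engine].screen, config.alpha))
        manifest["stages"]["diagnostics"] = diag

        # --------------------------------------------------- manifest
        for name, path in sorted(written.items()):
            manifest["files"][name] = {
                "sha256": _sha256(path),
                "rows": sum(1 for _ in open(path)) - 1,
            }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: %s", out)
        return out
    except Exception:
        logger.exception("pipeline failed; outputs in %s may be partial", out)
        (out / "FAILED").write_text("pipeline failed; see run.log\n")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
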