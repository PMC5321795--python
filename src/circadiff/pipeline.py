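"""End-to-end orchestration: simulate/load -> detect -> S_DR -> reports.

A run takes one resolved config (analysis thresholds plus either a simulation
block or input file paths) and writes all result tables into a run directory
together with a manifest recording the resolved config, the seed, package
version and per-table checksums. Identical config + seed reproduces
byte-identical tables; on any stage failure the partially written outputs are
removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import pandas as pd

from . import __version__
from .config import PipelineConfig, SimulationConfig, validate_config
from .detect import compute_rhythm_stats
from .io import read_matrix, write_matrix, write_table
from .report import (
    differential_expression,
    overlap_summary,
    phase_histogram,
    transition_categories,
)
from .sdr import RHYTHMIC_TIERS, differential_rhythmicity
from .simulate import generate_dataset

__all__ = ["run_pipeline"]

log = logging.getLogger("circadiff")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: Union[Mapping[str, Any], PipelineConfig],
    out_dir: Union[str, Path],
    sim_config: Optional[SimulationConfig] = None,
    matrix_path: Optional[Union[str, Path]] = None,
    samplesheet_path: Optional[Union[str, Path]] = None,
) -> dict[str, Any]:
    """Run the full analysis and write tables plus a manifest to ``out_dir``.

    Input is either a simulation config (the dataset is generated and written
    alongside the results) or paths to a matrix TSV + sample sheet TSV.
    Returns the manifest dictionary.
    """
    if isinstance(config, PipelineConfig):
        cfg = config.check()
    else:
        cfg, sim_from_raw = validate_config(config)
        sim_config = sim_config or sim_from_raw

    if sim_config is None and matrix_path is None:
        raise ValueError("provide either a simulation config or matrix/samplesheet paths")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        write_table(df, path)
        written.append(path)

    stage = "input"
    try:
        if sim_config is not None:
            stage = "simulate"
            tcm, truth = generate_dataset(sim_config)
            write_matrix(tcm, out / "matrix.tsv", out / "samples.tsv")
            written += [out / "matrix.tsv", out / "samples.tsv"]
            emit(truth.to_frame(), "sim_truth.tsv")
            log.info("simulated %d genes x %d samples", len(tcm.genes), len(tcm.samples))
        else:
            stage = "read"
            assert matrix_path is not None and samplesheet_path is not None
            tcm = read_matrix(matrix_path, samplesheet_path)

        cond_young, cond_old = tcm.conditions

        stage = f"detect[{cond_young}]"
        stats_young = compute_rhythm_stats(tcm, cond_young, cfg)
        emit(stats_young, f"rhythm_stats_{cond_young}.tsv")
        stage = f"detect[{cond_old}]"
        stats_old = compute_rhythm_stats(tcm, cond_old, cfg)
        emit(stats_old, f"rhythm_stats_{cond_old}.tsv")
        for name, df in ((cond_young, stats_young), (cond_old, stats_old)):
            n_r = int(df["tier"].isin(RHYTHMIC_TIERS).sum())
            log.info("%s: %d/%d genes rhythmic", name, n_r, len(df))

        stage = "sdr"
        diff = differential_rhythmicity(tcm, stats_young, stats_old, cfg)
        emit(diff, "differential_rhythmicity.tsv")
        log.info(
            "S_DR: %d included, %d excluded, %d llc, %d lost",
            int((diff["call"] != "excluded").sum()),
            int((diff["call"] == "excluded").sum()),
            int((diff["call"] == "llc").sum()),
            int((diff["call"] == "lost").sum()),
        )

        stage = "transitions"
        transitions = transition_categories(stats_young, stats_old, cfg)
        emit(transitions, "transitions.tsv")

        stage = "differential_expression"
        de = differential_expression(tcm, cfg)
        emit(de, "differential_expression.tsv")

        stage = "phase_histogram"
        hists = []
        for label, stats_df, genes in (
            (
                f"rhythmic_{cond_young}",
                stats_young,
                stats_young.loc[stats_young["tier"].isin(RHYTHMIC_TIERS), "gene_id"],
            ),
            (
                f"rhythmic_{cond_old}",
                stats_old,
                stats_old.loc[stats_old["tier"].isin(RHYTHMIC_TIERS), "gene_id"],
            ),
            (
                "llc",
                stats_old,
                diff.loc[diff["call"] == "llc", "gene_id"],
            ),
        ):
            hists.append(phase_histogram(stats_df, genes, label=label))
        emit(pd.concat(hists, ignore_index=True), "phase_histograms.tsv")

        stage = "manifest"
        overlap = overlap_summary(de, stats_young, stats_old)
        manifest: dict[str, Any] = {
            "version": __version__,
            "config": cfg.to_dict(),
            "simulation": None
            if sim_config is None
            else {**sim_config.__dict__, "zts": list(sim_config.zts), "conditions": list(sim_config.conditions)},
            "seed": None if sim_config is None else sim_config.seed,
            "inputs": None
            if matrix_path is None
            else {"matrix": str(matrix_path), "samplesheet": str(samplesheet_path)},
            "overlap_de_rhythmic": None if pd.isna(overlap) else overlap,
            "tables": {p.name: _sha256(p) for p in written},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
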