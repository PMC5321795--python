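"""Downstream summaries: rhythm transitions, phase shifters, phase-bin
histograms and time-averaged differential expression.

Classifies every gene into one transition category (highly rhythmic in one
age and arrhythmic in the other; rhythmic in both, flagging >= 2 h peak-time
shifts), histograms peak phases into the six 4-h sampling bins, and runs the
time-averaged differential-expression stand-in (all samples of an age as
replicates; Welch on log2(x+1); FDR 0.01, fold change >= 1.5, FPKM >= 1).
"""

from pathlib import Path

import pandas as pd

from circadiff import (
    PipelineConfig,
    differential_expression,
    overlap_summary,
    phase_histogram,
    read_matrix,
    read_table,
    transition_categories,
    write_table,
)
from circadiff.sdr import RHYTHMIC_TIERS

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"


def main() -> None:
    tcm = read_matrix(OUT / "matrix.tsv", OUT / "samples.tsv")
    young = read_table(OUT / "rhythm_stats_young.tsv")
    old = read_table(OUT / "rhythm_stats_old.tsv")
    sdr_res = read_table(OUT / "differential_rhythmicity.tsv")
    cfg = PipelineConfig()

    transitions = transition_categories(young, old, cfg)
    write_table(transitions, OUT / "transitions.tsv")
    print("transition categories:")
    for cat, n in transitions["category"].value_counts().items():
        print(f"  {cat:>30}: {n}")

    hists = []
    for label, stats_df, genes in (
        ("rhythmic_young", young, young.loc[young["tier"].isin(RHYTHMIC_TIERS), "gene_id"]),
        ("rhythmic_old", old, old.loc[old["tier"].isin(RHYTHMIC_TIERS), "gene_id"]),
        ("llc", old, sdr_res.loc[sdr_res["call"] == "llc", "gene_id"]),
    ):
        hists.append(phase_histogram(stats_df, genes, label=label))
    hist = pd.concat(hists, ignore_index=True)
    write_table(hist, OUT / "phase_histograms.tsv")

    de = differential_expression(tcm, cfg)
    write_table(de, OUT / "differential_expression.tsv")
    n_up = int((de["direction"] == "up").sum())
    n_down = int((de["direction"] == "down").sum())
    overlap = overlap_summary(de, young, old)
    print(f"differential expression: {n_up} up, {n_down} down (FDR {cfg.de_fdr}, FC >= {cfg.de_fold_change})")
    print(f"fraction of DE genes rhythmic in either age: {overlap:.3f}")


if __name__ == "__main__":
    main()
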