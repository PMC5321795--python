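"""Downstream summaries: rhythm transitions, phase shifts, phase histograms,
and a time-averaged differential-expression stand-in.

Transition categories compare rhythmicity tiers across the two conditions
(highly rhythmic in one, arrhythmic in the other; rhythmic in both; with
rhythmic-in-both genes further flagged as phase shifters at a >= 2 h circular
peak-time shift). The differential-expression step treats every sample of a
condition as a replicate — expression averaged over the day — and tests age
effects with a Welch t-test on log2(x+1) values, BH-corrected; it keeps the
published gates (FDR 0.01, fold change >= 1.5, mean FPKM >= 1 in at least one
condition) but is a model stand-in, not a read-count method.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .detect import PHASE_BIN_CENTERS, bin_phase
from .io import TimeCourseMatrix
from .sdr import RHYTHMIC_TIERS, bh_fdr

__all__ = [
    "phase_shift",
    "transition_categories",
    "phase_histogram",
    "differential_expression",
    "overlap_summary",
]

TRANSITION_CATEGORIES = (
    "rhythmic_young_arrhythmic_old",
    "rhythmic_old_arrhythmic_young",
    "phase_shifted",
    "rhythmic_both",
    "other",
)


def phase_shift(phase_a: float, phase_b: float, period: float = 24.0) -> float:
    """Circular distance between two peak phases, in hours, in [0, period/2]."""
    for p in (phase_a, phase_b):
        if not (0.0 <= p < period):
            raise ValueError(f"phase must lie in [0, {period}), got {p}")
    d = abs(phase_a - phase_b)
    return min(d, period - d)


def transition_categories(
    young_stats: pd.DataFrame,
    old_stats: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Classify every gene into exactly one rhythm-transition category.

    * ``rhythmic_young_arrhythmic_old`` — highly rhythmic in young, arrhythmic in old;
    * ``rhythmic_old_arrhythmic_young`` — the mirror image;
    * ``phase_shifted`` — rhythmic in both with a circular peak shift >= the
      configured threshold (default 2 h);
    * ``rhythmic_both`` — rhythmic in both, shift below threshold;
    * ``other`` — everything else.

    Output columns: gene_id, category, phase_shift_h (missing unless the gene
    is rhythmic in both conditions).
    """
    cfg = config or PipelineConfig()
    y = young_stats.set_index("gene_id")
    o = old_stats.set_index("gene_id")
    if set(y.index) != set(o.index):
        raise ValueError("young and old stats must cover the same genes")
    o = o.loc[y.index]

    rows = []
    for gene in y.index:
        ty, to = y.at[gene, "tier"], o.at[gene, "tier"]
        shift = np.nan
        if ty == "highly_rhythmic" and to == "arrhythmic":
            cat = "rhythmic_young_arrhythmic_old"
        elif to == "highly_rhythmic" and ty == "arrhythmic":
            cat = "rhythmic_old_arrhythmic_young"
        elif ty in RHYTHMIC_TIERS and to in RHYTHMIC_TIERS:
            shift = phase_shift(float(y.at[gene, "phase"]), float(o.at[gene, "phase"]), cfg.period)
            cat = "phase_shifted" if shift >= cfg.phase_shift_h else "rhythmic_both"
        else:
            cat = "other"
        rows.append({"gene_id": gene, "category": cat, "phase_shift_h": shift})
    return pd.DataFrame(rows)


def phase_histogram(
    stats_df: pd.DataFrame, subset: Optional[Iterable[str]] = None, label: str = "all"
) -> pd.DataFrame:
    """Counts and normalized fractions of peak phases per 4-h sampling bin.

    Output columns: bin, count, fraction, subset. With an empty subset, counts
    are zero and fractions missing.
    """
    df = stats_df.set_index("gene_id")
    if subset is not None:
        subset = list(subset)
        missing = [g for g in subset if g not in df.index]
        if missing:
            raise ValueError(f"subset genes not in stats: {missing[:5]}")
        df = df.loc[subset]
    counts = {b: 0 for b in PHASE_BIN_CENTERS}
    for ph in df["phase"]:
        counts[bin_phase(float(ph))] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "bin": list(counts),
            "count": list(counts.values()),
            "fraction": [c / total if total else np.nan for c in counts.values()],
            "subset": label,
        }
    )


def differential_expression(
    tcm: TimeCourseMatrix, config: Optional[PipelineConfig] = None
) -> pd.DataFrame:
    """Time-averaged differential expression between the two conditions.

    All samples of a condition are treated as replicates of its daily average.
    Genes with mean expression below 1 FPKM in both conditions are excluded
    from testing (p/q missing, direction "ns"); the rest get a Welch t-test on
    log2(x+1) with BH correction. Direction is up/down only when q passes the
    FDR gate and the mean fold change passes the fold-change gate.

    Output columns: gene_id, mean_young, mean_old, log2_fc, p_de, q_de, direction.
    """
    cfg = config or PipelineConfig()
    conds = tcm.conditions
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    c_young, c_old = conds
    Y = tcm.values[tcm.condition_samples(c_young).index].to_numpy(dtype=float)
    O = tcm.values[tcm.condition_samples(c_old).index].to_numpy(dtype=float)
    if Y.shape[1] < 2 or O.shape[1] < 2:
        raise ValueError("need >= 2 samples per condition")

    mean_y = Y.mean(axis=1)
    mean_o = O.mean(axis=1)
    tested = (mean_y >= cfg.min_median_fpkm) | (mean_o >= cfg.min_median_fpkm)

    with np.errstate(divide="ignore"):
        log2_fc = np.log2(mean_o) - np.log2(mean_y)

    p = np.full(len(mean_y), np.nan)
    if tested.any():
        t_res = stats.ttest_ind(
            np.log2(O[tested] + 1.0), np.log2(Y[tested] + 1.0), axis=1, equal_var=False
        )
        p_tested = np.nan_to_num(t_res.pvalue, nan=1.0)  # zero-variance ties -> no evidence
        p[tested] = np.clip(p_tested, np.finfo(float).tiny, 1.0)

    q = np.full(len(mean_y), np.nan)
    q[tested] = bh_fdr(p[tested])

    hi = np.maximum(mean_y, mean_o)
    lo = np.minimum(mean_y, mean_o)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / lo, np.inf)
    sig = tested & (q <= cfg.de_fdr) & (ratio >= cfg.de_fold_change)
    direction = np.where(sig & (mean_o > mean_y), "up", np.where(sig, "down", "ns"))

    return pd.DataFrame(
        {
            "gene_id": tcm.genes,
            "mean_young": mean_y,
            "mean_old": mean_o,
            "log2_fc": log2_fc,
            "p_de": p,
            "q_de": q,
            "direction": direction,
        }
    )


def overlap_summary(
    de: pd.DataFrame, young_stats: pd.DataFrame, old_stats: pd.DataFrame
) -> float:
    """Fraction of differentially expressed genes rhythmic in either condition.

    Returns NaN when there are no DE genes.
    """
    de_genes = de.loc[de["direction"] != "ns", "gene_id"]
    if de_genes.empty:
        return float("nan")
    y = young_stats.set_index("gene_id")["tier"]
    o = old_stats.set_index("gene_id")["tier"]
    rhythmic = {
        g
        for g in de_genes
        if y.get(g) in RHYTHMIC_TIERS or o.get(g) in RHYTHMIC_TIERS
    }
    return len(rhythmic) / len(de_genes)
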