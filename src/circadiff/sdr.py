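"""The differential rhythmicity score S_DR and late-life-cycler calling.

For each gene passing the inclusion filter, two condition-contrast statistics
are computed between a reference condition ("young") and a contrast condition
("old"):

* ``delta_P`` — the change in the rhythmicity score, (-log p_old) - (-log p_young),
  where p is the detector's rhythm p-value;
* ``delta_R`` — the log fold change of the effective amplitude (max - min
  expression), log(R_old / R_young).

Each is empirically Z-scored against its own distribution across genes
(sample mean/SD), and the differential rhythmicity score is

    S_DR = (Z_P + Z_R) / sqrt(2),

so that under independence of the two components S_DR is standard normal.
Tail probabilities come from a Gaussian fitted to the empirical S_DR
distribution — by default a robust (median/MAD) fit, so the fitted null
tracks the central bulk rather than the very outliers the score is meant to
flag — with Benjamini-Hochberg FDR control over the included genes.
A gene is called a late-life cycler ("llc") when its S_DR is significantly
above the fitted center and the gene is rhythmic in the contrast condition;
"lost" is the mirror-image call.

The log base never matters for S_DR: Z-scoring is invariant to affine
rescaling, so natural log and log10 give bit-near-identical scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .detect import condition_series
from .io import TimeCourseMatrix

__all__ = [
    "GaussianFit",
    "inclusion_filter",
    "delta_scores",
    "fit_gaussian",
    "zscore",
    "sdr",
    "sdr_pvalues",
    "bh_fdr",
    "differential_rhythmicity",
    "call_differential",
]

RHYTHMIC_TIERS = ("rhythmic", "highly_rhythmic")

RESULT_COLUMNS = [
    "gene_id",
    "delta_P",
    "delta_R",
    "z_P",
    "z_R",
    "s_DR",
    "p_sdr",
    "q_sdr",
    "call",
    "exclusion_reason",
]


@dataclass(frozen=True)
class GaussianFit:
    """Location/scale of a Gaussian fitted to an empirical distribution."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need >= 2 values for a Gaussian fit")
        if not (self.sd > 0):
            raise ValueError("degenerate empirical distribution (zero spread)")


def inclusion_filter(
    p_young: float,
    p_old: float,
    median_young: float,
    median_old: float,
    young_series: Sequence[float],
    old_series: Sequence[float],
    config: Optional[PipelineConfig] = None,
) -> tuple[bool, str]:
    """Decide whether a gene enters the differential-rhythmicity family.

    Included iff the detector p-value is < 1 in at least one condition, the
    median expression is >= 1 FPKM in at least one condition, and each
    condition has nonzero expression in at least one time point (guarding the
    amplitude log against division by zero). The reason names the first
    failed clause.
    """
    cfg = config or PipelineConfig()
    if not (p_young < 1.0 or p_old < 1.0):
        return False, "p-value = 1 in both conditions"
    if not (median_young >= cfg.min_median_fpkm or median_old >= cfg.min_median_fpkm):
        return False, f"median expression < {cfg.min_median_fpkm:g} FPKM in both conditions"
    if not np.max(np.asarray(young_series, dtype=float)) > 0:
        return False, "all-zero expression in young"
    if not np.max(np.asarray(old_series, dtype=float)) > 0:
        return False, "all-zero expression in old"
    return True, ""


def _log(x: np.ndarray, base: Optional[float]) -> np.ndarray:
    return np.log(x) if base is None else np.log(x) / math.log(base)


def delta_scores(
    p_young: float,
    p_old: float,
    amp_young: float,
    amp_old: float,
    log_base: Optional[float] = None,
) -> tuple[float, float]:
    """Per-gene contrasts: rhythmicity-score difference and amplitude log fold change.

    delta_P = (-log p_old) - (-log p_young); delta_R = log(R_old / R_young).
    Natural log by default; the base cancels after Z-scoring.
    """
    if amp_young <= 0 or amp_old <= 0:
        raise ValueError("zero effective amplitude reached delta_scores; inclusion filter breached")
    dP = float(-_log(np.asarray(p_old), log_base) + _log(np.asarray(p_young), log_base))
    dR = float(_log(np.asarray(amp_old), log_base) - _log(np.asarray(amp_young), log_base))
    return dP, dR


def fit_gaussian(values: Sequence[float], robust: bool = False) -> GaussianFit:
    """Gaussian fit to an empirical distribution.

    Default: sample mean and SD (ddof=1), the maximum-likelihood location and
    (bias-corrected) scale. ``robust=True`` uses median and normal-consistent
    MAD instead.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or not np.isfinite(v).all():
        raise ValueError("need >= 2 finite values")
    if robust:
        mean = float(np.median(v))
        sd = float(stats.median_abs_deviation(v, scale="normal"))
    else:
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
    return GaussianFit(mean=mean, sd=sd, n=int(v.size))


def zscore(values: Sequence[float], fit: GaussianFit) -> np.ndarray:
    """(x - mean) / sd elementwise."""
    return (np.asarray(values, dtype=float) - fit.mean) / fit.sd


def sdr(z_P: np.ndarray, z_R: np.ndarray) -> np.ndarray:
    """Combine the two Z-scores: (Z_P + Z_R) / sqrt(2)."""
    return (np.asarray(z_P, dtype=float) + np.asarray(z_R, dtype=float)) / math.sqrt(2.0)


def sdr_pvalues(
    s_values: Sequence[float],
    sided: str = "two",
    robust: bool = False,
) -> tuple[np.ndarray, GaussianFit]:
    """Tail probabilities for S_DR under a Gaussian fit to its own distribution.

    Two-sided (default): p = 2 * Phi(-|s - mean| / sd). One-sided: upper-tail
    probability, emphasising rhythm gains. p is clamped into (0, 1].
    """
    s = np.asarray(s_values, dtype=float)
    if s.size < 10:
        raise ValueError("need >= 10 values to fit the empirical S_DR distribution")
    fit = fit_gaussian(s, robust=robust)
    z = (s - fit.mean) / fit.sd
    if sided == "two":
        p = 2.0 * stats.norm.sf(np.abs(z))
    elif sided == "one":
        p = stats.norm.sf(z)
    else:
        raise ValueError(f"sided must be 'two' or 'one', got {sided!r}")
    return np.clip(p, np.finfo(float).tiny, 1.0), fit


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), capped at 1;
    order-preserving with the input. Every p must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not ((p > 0) & (p <= 1)).all():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def differential_rhythmicity(
    tcm: TimeCourseMatrix,
    young_stats: pd.DataFrame,
    old_stats: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Full per-gene differential-rhythmicity table with calls.

    ``young_stats`` is the reference condition, ``old_stats`` the contrast in
    which gains are called "llc". Excluded genes are kept in the output with
    an ``exclusion_reason`` and missing statistics so row counts reconcile
    with the input; the BH family is the included genes only. Rows are sorted
    by descending \\|S_DR\\| with excluded genes last.
    """
    cfg = config or PipelineConfig()
    y = young_stats.set_index("gene_id")
    o = old_stats.set_index("gene_id")
    if set(y.index) != set(o.index):
        raise ValueError("young and old stats must cover the same genes")
    genes = list(y.index)
    o = o.loc[genes]

    y_cond = str(y["condition"].iloc[0])
    o_cond = str(o["condition"].iloc[0])
    _, Y_young = condition_series(tcm, y_cond, cfg.period)
    _, Y_old = condition_series(tcm, o_cond, cfg.period)
    max_young = pd.Series(Y_young.max(axis=1), index=tcm.genes).loc[genes].to_numpy()
    max_old = pd.Series(Y_old.max(axis=1), index=tcm.genes).loc[genes].to_numpy()

    p_y = y["p_value"].to_numpy()
    p_o = o["p_value"].to_numpy()
    med_y = y["median_expr"].to_numpy()
    med_o = o["median_expr"].to_numpy()
    amp_y = y["eff_amplitude"].to_numpy()
    amp_o = o["eff_amplitude"].to_numpy()

    included = np.ones(len(genes), dtype=bool)
    reasons = np.full(len(genes), "", dtype=object)
    for i in range(len(genes)):
        ok, why = inclusion_filter(
            p_y[i], p_o[i], med_y[i], med_o[i], [max_young[i]], [max_old[i]], cfg
        )
        included[i] = ok
        reasons[i] = why

    out = pd.DataFrame(index=genes, columns=RESULT_COLUMNS[1:], dtype=object)
    out.index.name = "gene_id"
    out["call"] = "excluded"
    out["exclusion_reason"] = reasons

    if included.sum() >= 10:
        dP = np.empty(included.sum())
        dR = np.empty(included.sum())
        idx = np.flatnonzero(included)
        for k, i in enumerate(idx):
            dP[k], dR[k] = delta_scores(p_y[i], p_o[i], amp_y[i], amp_o[i], cfg.log_base)
        z_P = zscore(dP, fit_gaussian(dP))
        z_R = zscore(dR, fit_gaussian(dR))
        s = sdr(z_P, z_R)
        p_sdr, fit = sdr_pvalues(s, cfg.sdr_sided, robust=cfg.sdr_null_fit == "robust")
        q_sdr = bh_fdr(p_sdr)

        sub = pd.DataFrame(
            {
                "delta_P": dP,
                "delta_R": dR,
                "z_P": z_P,
                "z_R": z_R,
                "s_DR": s,
                "p_sdr": p_sdr,
                "q_sdr": q_sdr,
            },
            index=[genes[i] for i in idx],
        )
        for col in sub.columns:
            out.loc[sub.index, col] = sub[col]
        calls = call_differential(
            sub,
            y.loc[sub.index, "tier"],
            o.loc[sub.index, "tier"],
            fit,
            cfg,
        )
        out.loc[sub.index, "call"] = calls
    elif included.any():
        raise ValueError(
            f"only {int(included.sum())} genes pass the inclusion filter; "
            "need >= 10 to fit the empirical S_DR distribution"
        )

    out = out.reset_index()
    abs_s = pd.to_numeric(out["s_DR"], errors="coerce").abs()
    out = out.loc[abs_s.sort_values(ascending=False, na_position="last").index]
    out = out.reset_index(drop=True)
    for col in ("delta_P", "delta_R", "z_P", "z_R", "s_DR", "p_sdr", "q_sdr"):
        out[col] = pd.to_numeric(out[col])
    return out[RESULT_COLUMNS]


def call_differential(
    results: pd.DataFrame,
    young_tier: pd.Series,
    old_tier: pd.Series,
    fit: GaussianFit,
    config: Optional[PipelineConfig] = None,
) -> pd.Series:
    """Assign llc / lost / none from q-values, S_DR sign and rhythmicity tiers.

    llc: q <= FDR threshold, S_DR above the fitted center, and the gene is
    rhythmic (or highly rhythmic) in the contrast ("old") condition.
    lost: the mirror image, gated on rhythmicity in the reference condition.
    """
    cfg = config or PipelineConfig()
    sig = results["q_sdr"].to_numpy(dtype=float) <= cfg.sdr_fdr
    s = results["s_DR"].to_numpy(dtype=float)
    up = s > fit.mean
    down = s < fit.mean
    old_ok = old_tier.isin(RHYTHMIC_TIERS).to_numpy()
    young_ok = young_tier.isin(RHYTHMIC_TIERS).to_numpy()
    calls = np.full(len(results), "none", dtype=object)
    calls[sig & up & old_ok] = "llc"
    calls[sig & down & young_ok] = "lost"
    return pd.Series(calls, index=results.index)
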