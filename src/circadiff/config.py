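"""Pipeline and simulation configuration.

Defaults encode the study's published thresholds: a transcript is called
rhythmic at detector p <= 0.05 with peak/trough fold change >= 1.5 and median
expression >= 1 FPKM; "highly rhythmic" tightens the p cutoff to 0.01 and
"arrhythmic" means p > 0.5. Differential-rhythmicity calls use an FDR of
0.05, the time-averaged differential-expression stand-in an FDR of 0.01 with
fold change >= 1.5, and phase shifters require a >= 2 h circular shift.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields, asdict
from typing import Any, Mapping, Optional, Sequence

__all__ = ["PipelineConfig", "SimulationConfig", "validate_config"]


@dataclass
class PipelineConfig:
    """All analysis thresholds and detector choices.

    Attributes
    ----------
    rhythm_p : float
        Maximum detector p-value for a "rhythmic" call (default 0.05).
    highly_rhythmic_p : float
        Maximum p for "highly rhythmic" (default 0.01).
    arrhythmic_p : float
        Minimum p (exclusive) for "arrhythmic" (default 0.5).
    min_fold_change : float
        Minimum pseudo-counted peak/trough fold change (default 1.5).
    min_median_fpkm : float
        Minimum median expression for rhythmicity calls and for
        differential-rhythmicity inclusion (default 1 FPKM).
    sdr_fdr : float
        BH FDR threshold for differential-rhythmicity calls (default 0.05).
    de_fdr, de_fold_change : float
        Thresholds for the time-averaged differential-expression stand-in
        (defaults 0.01 and 1.5).
    phase_shift_h : float
        Minimum circular peak-time shift, in hours, to flag a phase shifter
        (default 2).
    period : float
        Rhythm period in hours (fixed-period cosinor; default 24).
    sdr_sided : str
        "two" (default) or "one": sidedness of the Gaussian tail probability
        assigned to each S_DR.
    sdr_null_fit : str
        How the Gaussian is fitted to the empirical S_DR distribution:
        "robust" (default; median and normal-consistent MAD, so the fit
        tracks the null bulk rather than the outliers the score is designed
        to flag) or "ml" (sample mean/SD).
    p_floor : float
        Lower clamp on detector p-values before taking logs.
    """

    rhythm_p: float = 0.05
    highly_rhythmic_p: float = 0.01
    arrhythmic_p: float = 0.5
    min_fold_change: float = 1.5
    min_median_fpkm: float = 1.0
    sdr_fdr: float = 0.05
    de_fdr: float = 0.01
    de_fold_change: float = 1.5
    phase_shift_h: float = 2.0
    period: float = 24.0
    sdr_sided: str = "two"
    log_base: Optional[float] = None  # None -> natural log
    sdr_null_fit: str = "robust"
    replicate_consistency_filter: bool = False
    p_floor: float = 1e-300

    def check(self) -> "PipelineConfig":
        if not (0 < self.highly_rhythmic_p <= self.rhythm_p):
            raise ValueError(
                "contradictory thresholds: highly_rhythmic_p "
                f"({self.highly_rhythmic_p}) must lie in (0, rhythm_p={self.rhythm_p}]"
            )
        if self.arrhythmic_p <= self.rhythm_p:
            raise ValueError(
                f"contradictory thresholds: arrhythmic_p ({self.arrhythmic_p}) "
                f"must exceed rhythm_p ({self.rhythm_p})"
            )
        if self.min_fold_change < 1:
            raise ValueError("min_fold_change must be >= 1")
        if self.sdr_sided not in ("two", "one"):
            raise ValueError(f"sdr_sided must be 'two' or 'one', got {self.sdr_sided!r}")
        if self.sdr_null_fit not in ("robust", "ml"):
            raise ValueError(f"sdr_null_fit must be 'robust' or 'ml', got {self.sdr_null_fit!r}")
        for name in ("sdr_fdr", "de_fdr"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.period <= 0:
            raise ValueError("period must be positive")
        return self

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class SimulationConfig:
    """Synthetic two-condition time-course design and gene-class mix.

    The default design mirrors a two-age circadian RNA-seq study: two
    conditions sampled every 4 h over one daily cycle (ZT 0..20) in two
    biological replicates. Noise is multiplicative lognormal with
    ``noise_sigma`` = 0.15 by default; baselines are drawn log-uniformly over
    ``baseline_range`` with a configurable fraction below 1 FPKM so the
    median-expression gate is exercised.
    """

    class_counts: dict[str, int] = field(default_factory=dict)
    conditions: Sequence[str] = ("young", "old")
    zts: Sequence[float] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    replicates: int = 2
    period: float = 24.0
    noise_sigma: float = 0.15
    baseline_range: tuple[float, float] = (1.0, 100.0)
    low_expression_fraction: float = 0.05
    low_expression_range: tuple[float, float] = (0.05, 0.9)
    amp_range: tuple[float, float] = (0.2, 0.8)
    llc_amplitude: float = 0.5
    llc_baseline_range: tuple[float, float] = (5.0, 100.0)
    phase_shift_min: float = 2.0
    amp_change_factor: float = 2.0
    de_fold: float = 2.0
    # the expressed transcriptome is mostly non-rhythmic; ~1/4 stable cyclers
    # matches the rhythmic fraction reported in fly-head RNA-seq
    null_flat_fraction: float = 0.75
    seed: int = 0

    VALID_CLASSES = (
        "stable_cycler",
        "llc",
        "lost",
        "phase_shift",
        "amp_change",
        "flat",
        "de_shift",
    )

    def check(self) -> "SimulationConfig":
        if not self.class_counts:
            raise ValueError("empty design: class_counts must name at least one gene class")
        unknown = [k for k in self.class_counts if k not in self.VALID_CLASSES]
        if unknown:
            raise ValueError(f"unknown gene classes {unknown}; valid: {self.VALID_CLASSES}")
        if any(n < 0 for n in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if sum(self.class_counts.values()) == 0:
            raise ValueError("empty design: all class counts are zero")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")
        if not self.zts or self.replicates < 1:
            raise ValueError("empty design: need >= 1 time point and >= 1 replicate")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo, hi = self.amp_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("amp_range must lie within [0, 1]")
        if not (0 <= self.llc_amplitude <= 1):
            raise ValueError("llc_amplitude must lie within [0, 1]")
        return self


_SIM_KEYS = {f.name for f in fields(SimulationConfig)}
_PIPE_KEYS = {f.name for f in fields(PipelineConfig)}


def validate_config(raw: Mapping[str, Any]) -> tuple[PipelineConfig, Optional[SimulationConfig]]:
    """Normalize a raw key-value config into dataclasses.

    Unknown keys are rejected with a closest-match suggestion; missing keys
    fall back to the published defaults; contradictory thresholds raise.
    A nested ``simulation`` mapping configures the synthetic-data generator.
    """
    raw = dict(raw or {})
    sim_raw = raw.pop("simulation", None)

    known = _PIPE_KEYS | {"simulation"}
    for key in raw:
        if key not in _PIPE_KEYS:
            raise ValueError(_unknown_key_msg(key, known))
    pipe = PipelineConfig(**raw).check()

    sim: Optional[SimulationConfig] = None
    if sim_raw is not None:
        sim_raw = dict(sim_raw)
        for key in sim_raw:
            if key not in _SIM_KEYS:
                raise ValueError(_unknown_key_msg(key, _SIM_KEYS))
        if "class_counts" in sim_raw:
            sim_raw["class_counts"] = dict(sim_raw["class_counts"])
        for tup_key in (
            "baseline_range",
            "low_expression_range",
            "amp_range",
            "llc_baseline_range",
        ):
            if tup_key in sim_raw:
                sim_raw[tup_key] = tuple(sim_raw[tup_key])
        sim = SimulationConfig(**sim_raw).check()
    return pipe, sim


def _unknown_key_msg(key: str, known: set[str]) -> str:
    hint = difflib.get_close_matches(key, sorted(known), n=1)
    suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
    return f"unknown config key {key!r}{suggestion}"
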