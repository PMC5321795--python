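"""Synthetic two-condition circadian expression time courses with known truth.

Each simulated gene follows a fixed-period cosine on a positive baseline with
multiplicative lognormal noise:

    x(g, c, r, t) = baseline_c * (1 + A_c * cos(2*pi*(t - phase_c)/period)) * exp(eps),
    eps ~ Normal(0, noise_sigma^2), independent per (gene, condition, replicate, time).

With relative amplitude A in [0, 1] the deterministic part is non-negative and
the lognormal factor is positive, so expression never goes below zero. Gene
classes encode the differential-rhythmicity ground truth: stably rhythmic in
both conditions, newly rhythmic in the second condition ("llc"), losing
rhythm, phase-shifted, amplitude-changed, flat, or flat with a baseline shift
between conditions ("de_shift", exercising time-averaged differential
expression).

Randomness is reproducible: each gene draws its parameters and noise from a
substream seeded by ``(seed, gene_index)``, so any subset of genes is
bit-reproducible independently of the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .io import TimeCourseMatrix

__all__ = ["GeneSimSpec", "SimTruth", "generate_dataset", "null_dataset"]


@dataclass(frozen=True)
class GeneSimSpec:
    """Generating parameters for one simulated gene.

    ``baseline``, ``rel_amplitude`` and ``phase`` map condition label to the
    per-condition parameter; ``noise_sigma`` is the log-scale noise s.d.
    """

    gene_id: str
    class_label: str
    baseline: dict[str, float]
    rel_amplitude: dict[str, float]
    phase: dict[str, float]
    noise_sigma: float


@dataclass
class SimTruth:
    """Truth table for a simulated dataset: per-gene specs plus the design."""

    specs: list[GeneSimSpec]
    seed: int
    conditions: tuple[str, ...]
    zts: tuple[float, ...]
    replicates: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.specs:
            row: dict[str, object] = {"gene_id": s.gene_id, "class_label": s.class_label}
            for c in self.conditions:
                row[f"baseline_{c}"] = s.baseline[c]
                row[f"rel_amplitude_{c}"] = s.rel_amplitude[c]
                row[f"phase_{c}"] = s.phase[c]
            row["noise_sigma"] = s.noise_sigma
            rows.append(row)
        return pd.DataFrame(rows)


def _draw_baseline(rng: np.random.Generator, config: SimulationConfig) -> float:
    """Log-uniform baseline; a configurable fraction falls below 1 FPKM."""
    if rng.random() < config.low_expression_fraction:
        lo, hi = config.low_expression_range
    else:
        lo, hi = config.baseline_range
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_spec(
    gene_id: str, class_label: str, rng: np.random.Generator, config: SimulationConfig
) -> GeneSimSpec:
    cond_a, cond_b = config.conditions  # e.g. young, old
    phase = float(rng.uniform(0.0, config.period))

    if class_label in ("llc", "lost"):
        lo, hi = config.llc_baseline_range
        base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    else:
        base = _draw_baseline(rng, config)
    baselines = {cond_a: base, cond_b: base}
    phases = {cond_a: phase, cond_b: phase}

    if class_label == "flat":
        amps = {cond_a: 0.0, cond_b: 0.0}
    elif class_label == "stable_cycler":
        a = float(rng.uniform(*config.amp_range))
        amps = {cond_a: a, cond_b: a}
    elif class_label == "llc":
        amps = {cond_a: 0.0, cond_b: config.llc_amplitude}
    elif class_label == "lost":
        amps = {cond_a: config.llc_amplitude, cond_b: 0.0}
    elif class_label == "phase_shift":
        a = float(rng.uniform(*config.amp_range))
        amps = {cond_a: a, cond_b: a}
        shift = float(rng.uniform(config.phase_shift_min, config.period / 2))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        phases[cond_b] = (phase + sign * shift) % config.period
    elif class_label == "amp_change":
        a = float(rng.uniform(*config.amp_range))
        amps = {cond_a: a, cond_b: min(1.0, a * config.amp_change_factor)}
    elif class_label == "de_shift":
        amps = {cond_a: 0.0, cond_b: 0.0}
        baselines[cond_b] = base * config.de_fold
    else:  # pragma: no cover - guarded by SimulationConfig.check
        raise ValueError(f"unknown class label {class_label!r}")

    return GeneSimSpec(
        gene_id=gene_id,
        class_label=class_label,
        baseline=baselines,
        rel_amplitude=amps,
        phase=phases,
        noise_sigma=config.noise_sigma,
    )


def expected_expression(spec: GeneSimSpec, condition: str, t: np.ndarray, period: float = 24.0) -> np.ndarray:
    """Noiseless expression of a gene at times ``t`` (hours) in one condition."""
    return spec.baseline[condition] * (
        1.0
        + spec.rel_amplitude[condition]
        * np.cos(2.0 * np.pi * (np.asarray(t, dtype=float) - spec.phase[condition]) / period)
    )


def generate_dataset(config: SimulationConfig) -> tuple[TimeCourseMatrix, SimTruth]:
    """Simulate an expression matrix plus truth table from a class mix.

    Gene order follows ``config.class_counts`` insertion order. Sample columns
    are condition-major, then replicate, then ZT.
    """
    config.check()
    conds = tuple(config.conditions)
    zts = np.asarray(config.zts, dtype=float)
    reps = range(1, config.replicates + 1)

    sample_ids, meta_rows = [], []
    for c in conds:
        for r in reps:
            for zt in zts:
                sid = f"{c}_r{r}_ZT{zt:g}"
                sample_ids.append(sid)
                meta_rows.append({"sample_id": sid, "condition": c, "replicate": r, "zt": zt})
    samples = pd.DataFrame(meta_rows).set_index("sample_id")

    specs: list[GeneSimSpec] = []
    values = np.empty((sum(config.class_counts.values()), len(sample_ids)))
    idx = 0
    for class_label, count in config.class_counts.items():
        for _ in range(count):
            gene_id = f"g{idx:05d}_{class_label}"
            rng = np.random.default_rng([config.seed, idx])
            spec = _draw_spec(gene_id, class_label, rng, config)
            row = []
            for c in conds:
                for _r in reps:
                    mean = expected_expression(spec, c, zts, config.period)
                    eps = rng.standard_normal(len(zts)) * config.noise_sigma
                    row.append(mean * np.exp(eps))
            values[idx] = np.clip(np.concatenate(row), 0.0, None)
            specs.append(spec)
            idx += 1

    vals = pd.DataFrame(values, index=[s.gene_id for s in specs], columns=sample_ids)
    truth = SimTruth(
        specs=specs,
        seed=config.seed,
        conditions=conds,
        zts=tuple(float(z) for z in zts),
        replicates=config.replicates,
    )
    return TimeCourseMatrix(values=vals, samples=samples), truth


def null_dataset(n_genes: int, config: Optional[SimulationConfig] = None) -> tuple[TimeCourseMatrix, SimTruth]:
    """Simulate a dataset with zero true differential-rhythmicity effect.

    Every gene has identical generating parameters in both conditions — a
    configurable mix of flat genes and stable cyclers — so any differential
    call downstream is a false positive.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    config = config or SimulationConfig()
    n_flat = int(round(n_genes * config.null_flat_fraction))
    counts = {"flat": n_flat, "stable_cycler": n_genes - n_flat}
    counts = {k: v for k, v in counts.items() if v > 0}
    return generate_dataset(replace(config, class_counts=counts))
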