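import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from circadiff.config import SimulationConfig
from circadiff.io import TimeCourseMatrix
from circadiff.simulate import generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

ZTS = [0.0, 4.0, 8.0, 12.0, 16.0, 20.0]


def build_matrix(gene_values: dict[str, dict[str, list[float]]]) -> TimeCourseMatrix:
    """Hand-build a 2x2x6 TimeCourseMatrix from per-gene, per-condition
    12-value series (replicate 1 then replicate 2, each over ZT 0..20)."""
    sample_ids, meta = [], []
    for cond in ("young", "old"):
        for rep in (1, 2):
            for zt in ZTS:
                sid = f"{cond}_r{rep}_ZT{zt:g}"
                sample_ids.append(sid)
                meta.append({"sample_id": sid, "condition": cond, "replicate": rep, "zt": zt})
    rows = {}
    for gene, series in gene_values.items():
        rows[gene] = list(series["young"]) + list(series["old"])
    vals = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    return TimeCourseMatrix(values=vals, samples=pd.DataFrame(meta).set_index("sample_id"))


def cosine_series(baseline: float, amp: float, phase: float, period: float = 24.0) -> list[float]:
    """Noiseless two-replicate series (12 values) for one condition."""
    t = np.array(ZTS * 2)
    return list(baseline * (1 + amp * np.cos(2 * np.pi * (t - phase) / period)))


# 12-point series with fixed statistics: cosinor p ~ 0.036 (rhythmic but not
# highly rhythmic), pseudo-counted fold change ~ 1.72, median ~ 9.5
MID_P_SERIES = [
    8.602, 11.359, 9.449, 13.534, 8.378, 5.709,
    9.224, 10.405, 13.882, 10.126, 9.382, 9.631,
]

# pseudo-count worked example: c = 2, FC = (6+2)/(0+2) = 4
PSEUDO_SERIES = [0.0, 0.0, 2.0, 4.0, 6.0, 4.0]


@pytest.fixture(scope="session")
def demo_dataset():
    """Small mixed-class simulation shared across tests."""
    sim = SimulationConfig(
        class_counts={
            "stable_cycler": 60,
            "flat": 60,
            "llc": 15,
            "lost": 15,
            "phase_shift": 15,
            "amp_change": 15,
            "de_shift": 20,
        },
        seed=11,
    )
    return generate_dataset(sim)


@pytest.fixture()
def toy_gate_matrix():
    """Eight hand-built genes, one per classification/exclusion gate."""
    strong = cosine_series(10.0, 0.5, 8.0)
    weak = cosine_series(10.0, 0.05, 8.0)
    low = cosine_series(0.5, 0.8, 8.0)
    sub_median = cosine_series(0.6, 0.3, 4.0)
    genes = {
        "low_median_cycler": {"young": low, "old": low},
        "small_fc_cycler": {"young": weak, "old": weak},
        "strong_cycler": {"young": strong, "old": strong},
        "flat_constant": {"young": [5.0] * 12, "old": [5.0] * 12},
        "old_all_zero": {"young": strong, "old": [0.0] * 12},
        "pseudo_count": {"young": PSEUDO_SERIES * 2, "old": PSEUDO_SERIES * 2},
        "mid_p_cycler": {"young": MID_P_SERIES, "old": MID_P_SERIES},
        "sub_median_both": {"young": sub_median, "old": sub_median},
    }
    return build_matrix(genes)
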