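import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from circadiff.config import PipelineConfig, SimulationConfig
from circadiff.detect import compute_rhythm_stats
from circadiff.sdr import (
    GaussianFit,
    bh_fdr,
    delta_scores,
    differential_rhythmicity,
    fit_gaussian,
    inclusion_filter,
    sdr,
    sdr_pvalues,
    zscore,
)
from circadiff.simulate import generate_dataset, null_dataset


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up definition applied literally:
    q_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            p_sorted[j] * m / (j + 1) for j in range(m) if p_sorted[j] >= p_sorted[i]
        )
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestDeltaScores:
    def test_symmetry_zero(self):
        assert delta_scores(0.3, 0.3, 5.0, 5.0) == (0.0, 0.0)

    def test_closed_form(self):
        dP, dR = delta_scores(0.5, 0.005, 2.0, 20.0)
        assert dP == pytest.approx(math.log(100), rel=1e-12)
        assert dR == pytest.approx(math.log(10), rel=1e-12)

    @given(
        st.floats(min_value=1e-10, max_value=1.0),
        st.floats(min_value=1e-10, max_value=1.0),
        st.floats(min_value=1e-6, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_swapping_conditions_negates_deltas(self, py, po, ry, ro):
        dP, dR = delta_scores(py, po, ry, ro)
        dP_sw, dR_sw = delta_scores(po, py, ro, ry)
        assert dP_sw == -dP and dR_sw == -dR

    def test_zero_amplitude_is_hard_error(self):
        with pytest.raises(ValueError, match="inclusion filter"):
            delta_scores(0.5, 0.5, 0.0, 1.0)


class TestGaussianFitAndZscore:
    def test_two_point_closed_form(self):
        fit = fit_gaussian([-1.0, 1.0])
        assert fit.mean == 0.0
        assert fit.sd == pytest.approx(math.sqrt(2))
        assert fit.n == 2

    def test_degenerate_spread_raises(self):
        with pytest.raises(ValueError, match="degenerate|spread"):
            fit_gaussian([5.0, 5.0, 5.0])

    def test_monte_carlo_consistency(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(3, 2, 100_000)
        fit = fit_gaussian(draws)
        se_mean = 2 / math.sqrt(draws.size)
        se_sd = 2 / math.sqrt(2 * draws.size)
        assert abs(fit.mean - 3) < 3 * se_mean
        assert abs(fit.sd - 2) < 3 * se_sd

    def test_zscore_example(self):
        z = zscore([2.0, 4.0], GaussianFit(mean=3.0, sd=1.0, n=2))
        assert z.tolist() == [-1.0, 1.0]

    def test_self_fit_idempotence(self):
        rng = np.random.default_rng(3)
        v = rng.normal(5, 7, 200)
        z1 = zscore(v, fit_gaussian(v))
        z2 = zscore(z1, fit_gaussian(z1))
        assert np.allclose(z1, z2, atol=1e-10)

    def test_affine_invariance_of_self_fit_zscores(self):
        """Any affine transform of the inputs leaves self-fit Z-scores
        unchanged — this is why the log base cannot affect S_DR."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = rng.normal(0, 3, 50)
            a, b = rng.uniform(0.1, 10), rng.uniform(-5, 5)
            z = zscore(v, fit_gaussian(v))
            z_affine = zscore(a * v + b, fit_gaussian(a * v + b))
            assert np.allclose(z, z_affine, atol=1e-10)


class TestSdrCombination:
    @pytest.mark.parametrize(
        "zp,zr,expected",
        [(1.0, 1.0, math.sqrt(2)), (0.0, 0.0, 0.0), (1.0, -1.0, 0.0)],
    )
    def test_closed_forms(self, zp, zr, expected):
        assert sdr(np.array([zp]), np.array([zr]))[0] == pytest.approx(expected, abs=1e-12)


class TestSdrPvalues:
    def test_center_has_p_one(self):
        s = np.concatenate([np.linspace(-2, 2, 20), [0.0]])
        s = s - s.mean()
        p, fit = sdr_pvalues(s)
        center = np.argmin(np.abs(s - fit.mean))
        assert p[center] == pytest.approx(1.0, abs=1e-6)

    def test_normal_quantile(self):
        rng = np.random.default_rng(5)
        s = rng.normal(0, 1, 5000)
        _, fit = sdr_pvalues(s)
        target = fit.mean + 1.959964 * fit.sd
        p, _ = sdr_pvalues(np.concatenate([s, [target]]))
        # appending one point barely moves the fit
        assert p[-1] == pytest.approx(0.05, abs=2e-3)

    def test_matches_erfc_oracle(self):
        rng = np.random.default_rng(6)
        s = rng.normal(1.0, 2.0, 500)
        p, fit = sdr_pvalues(s)
        z = np.abs((s - fit.mean) / fit.sd)
        oracle = np.array([math.erfc(zi / math.sqrt(2)) for zi in z])
        assert np.allclose(p, oracle, atol=1e-12, rtol=0)

    def test_probability_integral_transform_uniform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(7)
        p, _ = sdr_pvalues(rng.normal(0, 1, 10_000))
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_one_sided_mode(self):
        rng = np.random.default_rng(8)
        s = rng.normal(0, 1, 1000)
        p, fit = sdr_pvalues(s, sided="one")
        assert (p[s > fit.mean] < 0.5).all()
        assert (p[s < fit.mean] > 0.5).all()


class TestBhFdr:
    def test_hand_worked_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(q, 0.05)

    def test_single_value(self):
        assert bh_fdr([1.0]).tolist() == [1.0]

    def test_ties_take_larger_rank(self):
        assert np.allclose(bh_fdr([0.02, 0.02]), [0.02, 0.02])

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            n = rng.integers(1, 13)
            p = rng.uniform(1e-6, 1.0, n)
            q = bh_fdr(p)
            assert np.array_equal(q, brute_force_bh(p))

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, rng.integers(2, 200))
            assert np.allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.1]):
            with pytest.raises(ValueError):
                bh_fdr(bad)


class TestInclusionFilter:
    def test_passing_gene(self):
        ok, why = inclusion_filter(0.3, 0.2, 5.0, 6.0, [1.0], [1.0])
        assert ok and why == ""

    def test_p_one_in_both(self):
        ok, why = inclusion_filter(1.0, 1.0, 5.0, 6.0, [1.0], [1.0])
        assert not ok and "p-value" in why

    def test_median_below_floor_in_both(self):
        ok, why = inclusion_filter(0.3, 0.2, 0.4, 0.7, [1.0], [1.0])
        assert not ok and "median" in why

    def test_all_zero_series(self):
        ok, why = inclusion_filter(0.3, 1.0, 5.0, 6.0, [2.0], [0.0])
        assert not ok and "old" in why
        ok, why = inclusion_filter(1.0, 0.3, 5.0, 6.0, [0.0], [2.0])
        assert not ok and "young" in why


@pytest.fixture(scope="module")
def mixed_run():
    sim = SimulationConfig(
        class_counts={"stable_cycler": 150, "flat": 150, "llc": 30, "lost": 30},
        seed=31,
    )
    tcm, truth = generate_dataset(sim)
    young = compute_rhythm_stats(tcm, "young")
    old = compute_rhythm_stats(tcm, "old")
    return tcm, truth, young, old


class TestDifferentialRhythmicity:
    def test_row_counts_reconcile_and_excluded_annotated(self, mixed_run):
        tcm, _, young, old = mixed_run
        res = differential_rhythmicity(tcm, young, old)
        assert len(res) == len(tcm.genes)
        excluded = res[res["call"] == "excluded"]
        assert (excluded["exclusion_reason"] != "").all()
        assert excluded["s_DR"].isna().all()
        kept = res[res["call"] != "excluded"]
        assert kept["s_DR"].notna().all()

    def test_self_normalization(self, mixed_run):
        tcm, _, young, old = mixed_run
        res = differential_rhythmicity(tcm, young, old)
        s = res["s_DR"].dropna().to_numpy()
        assert abs(s.mean()) < 1e-9
        assert 0.7 < s.std(ddof=1) < 1.3

    def test_sorted_by_descending_abs_sdr(self, mixed_run):
        tcm, _, young, old = mixed_run
        res = differential_rhythmicity(tcm, young, old)
        s = res["s_DR"].abs().dropna().to_numpy()
        assert (np.diff(s) <= 1e-12).all()

    def test_condition_swap_negates_scores(self, mixed_run):
        tcm, _, young, old = mixed_run
        fwd = differential_rhythmicity(tcm, young, old).set_index("gene_id")
        rev = differential_rhythmicity(tcm, old, young).set_index("gene_id")
        genes = fwd.index[fwd["call"] != "excluded"]
        for col in ("delta_P", "delta_R", "s_DR"):
            assert np.array_equal(
                fwd.loc[genes, col].to_numpy(dtype=float),
                -rev.loc[genes, col].to_numpy(dtype=float),
            )

    def test_log_base_choice_is_immaterial(self, mixed_run):
        tcm, _, young, old = mixed_run
        nat = differential_rhythmicity(tcm, young, old, PipelineConfig(log_base=None))
        b10 = differential_rhythmicity(tcm, young, old, PipelineConfig(log_base=10.0))
        s_nat = nat.set_index("gene_id")["s_DR"].dropna()
        s_b10 = b10.set_index("gene_id")["s_DR"].dropna()
        assert np.allclose(s_nat.to_numpy(), s_b10.loc[s_nat.index].to_numpy(), atol=1e-12)

    def test_llc_and_lost_calls_respect_gates(self, mixed_run):
        tcm, truth, young, old = mixed_run
        res = differential_rhythmicity(tcm, young, old).set_index("gene_id")
        o = old.set_index("gene_id")
        y = young.set_index("gene_id")
        for gene, row in res[res["call"] == "llc"].iterrows():
            assert row["q_sdr"] <= 0.05
            assert o.at[gene, "tier"] in ("rhythmic", "highly_rhythmic")
        for gene, row in res[res["call"] == "lost"].iterrows():
            assert row["q_sdr"] <= 0.05
            assert y.at[gene, "tier"] in ("rhythmic", "highly_rhythmic")

    def test_implanted_llc_genes_score_high(self, mixed_run):
        tcm, truth, young, old = mixed_run
        res = differential_rhythmicity(tcm, young, old).set_index("gene_id")
        llc_truth = [s.gene_id for s in truth.specs if s.class_label == "llc"]
        called = set(res[res["call"] == "llc"].index)
        sensitivity = len(called & set(llc_truth)) / len(llc_truth)
        assert sensitivity >= 0.8

    def test_fdr_zero_calls_nothing(self, mixed_run):
        tcm, _, young, old = mixed_run
        res = differential_rhythmicity(tcm, young, old, PipelineConfig(sdr_fdr=0.0))
        assert set(res["call"]) <= {"none", "excluded"}


def test_null_dataset_false_positive_rate_controlled():
    """On data with zero true effect, llc/lost calls stay near or below the
    FDR level (3 seeds here; the acceptance suite runs 20)."""
    rates = []
    for seed in (101, 102, 103):
        tcm, _ = null_dataset(800, SimulationConfig(seed=seed))
        young = compute_rhythm_stats(tcm, "young")
        old = compute_rhythm_stats(tcm, "old")
        res = differential_rhythmicity(tcm, young, old)
        kept = res[res["call"] != "excluded"]
        rates.append((kept["call"] != "none").mean())
    assert np.mean(rates) <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / (3 * 800))
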