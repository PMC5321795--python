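# Methods

## Model and procedure

`circadiff` analyses a gene × sample matrix of non-negative, FPKM-like
expression values from a balanced two-condition design: every condition has
the same replicate × Zeitgeber-time grid (default 2 conditions × 2 biological
replicates × 6 time points at ZT 0, 4, 8, 12, 16, 20). Balance is enforced at
read time because the downstream empirical Z-scoring assumes all genes share
one sampling grid.

### Rhythm detection

Per gene and condition, the replicates are arranged as consecutive daily
cycles (replicate *r* at t = ZT + (r−1)·24) and fitted by ordinary least
squares with a single fixed-period harmonic:

    y(t) = m + a·cos(2πt/24) + b·sin(2πt/24)

The p-value is the F test of this model against intercept-only with
(2, n−3) degrees of freedom; amplitude = √(a²+b²); the peak phase is
(24/2π)·atan2(b, a) mod 24; m is the mesor. For a fixed 24-h period the
cycle offset is mathematically identical to duplicated phase points, so the
arrangement is conventional, not consequential (asserted in tests). The
detector sits behind a minimal contract — (p, phase, amplitude) per gene —
so rank-based periodicity tests (JTK-style) can be plugged in without
touching anything downstream.

Assumptions: one dominant 24-h harmonic (no period scanning, no detrending,
no multi-harmonic fits); approximately homoscedastic errors on the raw scale
within a gene. The F test is exact under Gaussian noise; under the
generator's multiplicative lognormal noise at σ = 0.15 it remains uniform to
within KS detection at n = 10,000 (verified in the acceptance checks).

Classification gates (defaults; all configurable in `PipelineConfig`):

| gate | default | meaning |
|---|---|---|
| `min_median_fpkm` | 1 FPKM | median of the condition's 12 samples |
| `min_fold_change` | 1.5 | pseudo-counted max/min (below) |
| `rhythm_p` | 0.05 | rhythmic |
| `highly_rhythmic_p` | 0.01 | highly rhythmic |
| `arrhythmic_p` | 0.5 | arrhythmic iff p > 0.5 |

The peak/trough fold change adds a pseudo-count — the smallest nonzero value
of the series — to both max and min, so all-zero or zero-trough series never
divide by zero; an all-zero series has fold change 1 by convention. Tier
order: the median gate trumps everything (`low_expression`), then
highly-rhythmic/rhythmic, then arrhythmic, else `indeterminate` (e.g. a
small-amplitude gene with tiny p but fold change < 1.5).

Degenerate (zero-variance) series are not errors: they are fitted as p = 1,
amplitude 0, phase 0 with a flag, so one constant gene cannot abort a batch.
Detector p-values are floored at 1e-300 before any log.

### Differential rhythmicity

Genes enter the scored family when (i) the detector p < 1 in at least one
condition, (ii) median expression ≥ 1 FPKM in at least one condition, and
(iii) each condition has nonzero expression somewhere (so the amplitude log
is defined). Excluded genes stay in the output with the first failed clause
as `exclusion_reason`, so row counts always reconcile.

Per included gene, with young as reference and old as contrast:

    ΔP = (−log p_old) − (−log p_young)
    ΔR = log(R_old / R_young),   R = max − min expression ("effective amplitude")

Natural log by default. The base is immaterial for the score: a base change
is an affine rescaling, and self-fit Z-scores are affine-invariant (asserted
to 1e−12 in tests); it only changes the printed ΔP/ΔR values.

ΔP and ΔR are each Z-scored against their own empirical distribution across
the family (sample mean/SD — the definition of a Z-score), and combined as

    S_DR = (Z_P + Z_R) / √2

which is standard normal when the two components are independent. On real
mixtures they are positively correlated (the same noise that sharpens a fit
also stretches the range), so the realized S_DR spread can exceed 1; the
self-normalization tests therefore assert mean ≈ 0 exactly and sd within
[0.7, 1.3] on mixtures, tightening to [0.9, 1.1] when independence is forced
by permutation.

**Gaussian fit for p-values.** Each S_DR gets a two-sided tail probability
under a Gaussian fitted to the empirical S_DR distribution. The default fit
is robust — median location, normal-consistent MAD scale
(`sdr_null_fit: robust`) — because the empirical distribution contains the
very outliers the score is designed to flag, plus heavy tails from strongly
rhythmic genes whose −log p difference is intrinsically high-variance; the
maximum-likelihood moments absorb both and shrink every Z. With the robust
fit the null false-call rate stays far below the FDR level (≈ 5·10⁻⁴
measured over 20 × 2,000 zero-effect genes) while implanted de-novo cyclers
are recovered with sensitivity ≳ 0.95. `sdr_null_fit: ml` restores plain
mean/SD. Sidedness is configurable (`sdr_sided: two|one`); two-sided is the
default, with the sign of S_DR − center deciding gain versus loss.

BH FDR is computed over the included family only (filter-then-test). The
step-up is implemented directly as q = min over p₍ⱼ₎ ≥ p₍ᵢ₎ of p₍ⱼ₎·m/rank(j)
(reverse cumulative minimum), which matches the brute-force definition
bit-exactly and statsmodels' `fdr_bh` to 1e−12 (both asserted).

Calls: **llc** iff q ≤ 0.05, S_DR above the fitted center, and old tier
rhythmic/highly rhythmic; **lost** is the mirror image gated on the young
tier. The output table is sorted by descending |S_DR|.

### Reports

* **Transitions** — `rhythmic_young_arrhythmic_old` (highly rhythmic young,
  arrhythmic old), the mirror category, `rhythmic_both`, with rhythmic-both
  genes flagged `phase_shifted` at a circular peak shift ≥ 2 h
  (min(|Δ|, 24−|Δ|)), else `other`. Every gene lands in exactly one category.
* **Phase histograms** — integer-rounded phases binned into (4n−2, 4n+2]
  around the six sampled times, half-open at the top (so hour 2 → bin 0,
  hour 22 → bin 20, hour 23 wraps to bin 0), with round-half-up (23.5 → 0).
  The interval-endpoint convention is exposed in the code and pinned by an
  enumeration test: the 24 integer hours partition into 6 bins of 4.
* **Differential expression (stand-in)** — the published count-model step is
  out of scope; the stand-in keeps its design logic (all 12 samples of an
  age as replicates of the daily average) and gates (FDR 0.01, fold change
  ≥ 1.5, mean ≥ 1 FPKM in either age) but tests with Welch's t on log2(x+1).
  It is calibrated and sensitive on the generator (≤ 1% null calls; ≥ 0.95
  sensitivity at baseline ratio 2, σ = 0.15) and is not expected to
  reproduce read-level results. An optional replicate-consistency filter is
  documented but off by default.

## Synthetic data

The generator emulates a two-age circadian RNA-seq design. Gene expression is

    x(g,c,r,t) = baseline_c · (1 + A_c·cos(2π(t − φ_c)/24)) · exp(ε),
    ε ~ N(0, σ²) i.i.d. per (gene, condition, replicate, time)

with relative amplitude A ∈ [0,1], so values are strictly positive.
Multiplicative lognormal noise (default σ = 0.15) mimics FPKM dispersion and
keeps non-negativity without clipping. Baselines are log-uniform on 1–100
FPKM with 5% of genes drawn below 1 FPKM so the median gate is exercised;
de-novo cycler ("llc") and rhythm-loser baselines are drawn on 5–100 FPKM.
The relative-amplitude parameterization gives an analytic handle on the
fold-change gate: noiseless FC = (1+A)/(1−A), so FC 1.5 ↔ A = 0.2.

Gene classes: `stable_cycler` (same A, φ both ages), `llc` (A: 0 → 0.5),
`lost` (the reverse), `phase_shift` (equal A, circular shift ≥ 2 h, direction
random), `amp_change` (A doubled, capped at 1), `flat`, and `de_shift` (flat,
baseline doubled in old — exercises the DE stand-in). `null_dataset` mixes
flat genes and stable cyclers with identical parameters in both ages; the
default mix is 25% stable cyclers, matching the ~20–25% rhythmic fraction
observed in fly-head circadian transcriptomes (the earlier 50/50 strawman
overweights strongly rhythmic genes, whose −log p differences dominate the
empirical null).

Randomness: every gene draws parameters and noise from
`default_rng([seed, gene_index])`, so datasets are bit-reproducible and any
prefix subset of genes is independent of the rest.

What the generator does **not** emulate: count noise (no negative-binomial
read model), library-size or batch artifacts, isoform structure, correlated
genes, non-sinusoidal waveforms, and unequal-variance replicates. Passing
tests therefore demonstrate the statistical machinery under the stated
model, not robustness to every artifact of real RNA-seq.

## Problem sizes used in tests

The acceptance checks run 20 simulated studies of 2,000 genes for null
calibration and for recovery (50 implanted de-novo cyclers among 1,950
nulls), 10,000 flat genes for detector calibration, and 1,000 noisy cyclers
for phase recovery — sizes at which the binomial error of the measured rates
is well inside the asserted bounds. The whole suite and the acceptance
script each complete in well under a minute on one CPU.

## Known limitations

* The period is fixed (24 h default); no period estimation.
* S_DR compares exactly two conditions; multi-condition designs need
  pairwise runs.
* The Gaussian-fit p-values are calibrated against the empirical bulk; if a
  large fraction of genes carries true differential rhythmicity, the robust
  fit too will be contaminated and calls become conservative.
* Excluding a gene in one age but not the other (e.g. expressed only in old)
  is handled by the inclusion filter's "either condition" clauses, but the
  score itself still needs a nonzero amplitude in both ages.
* Isoform-level corroboration of gene-level calls is not implemented;
  gene-level matrices only.
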