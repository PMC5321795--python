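# circadiff

Differential rhythmicity analysis for two-condition circadian expression time
courses — e.g. heads of young versus old flies sampled around the clock.
`circadiff` detects 24-h transcript rhythms per condition, scores each gene's
*change* in rhythmicity between the conditions, and calls genes that gain
rhythmic expression ("late-life cyclers", LLCs), lose it, or shift their peak
phase. A synthetic-data generator with known per-gene truth makes the whole
pipeline testable without sequencing data.

## The method

**Rhythm detection.** For each gene and condition, the two biological
replicates (6 time points each, ZT 0, 4, …, 20) are arranged as consecutive
daily cycles and fitted with a fixed-period cosinor,

```
y(t) = m + a·cos(2πt/24) + b·sin(2πt/24)
```

with a p-value from the F statistic against the intercept-only model on
(2, n−3) degrees of freedom; amplitude is √(a²+b²) and the peak phase
(acrophase) is (24/2π)·atan2(b, a) mod 24. A gene is called **rhythmic** when
median expression ≥ 1 FPKM, pseudo-counted peak/trough fold change ≥ 1.5 and
p ≤ 0.05; **highly rhythmic** tightens p to ≤ 0.01; **arrhythmic** means
p > 0.5.

**Differential rhythmicity score.** For each gene passing the inclusion
filter (p < 1 in either condition, median ≥ 1 FPKM in either condition,
nonzero expression in both), two contrasts are computed:

```
ΔP = (−log p_old) − (−log p_young)        # change in rhythmicity score
ΔR = log(R_old / R_young)                 # R = max − min expression
```

Each is Z-scored against its empirical distribution across genes, and

```
S_DR = (Z_P + Z_R) / √2
```

so that S_DR is standard normal when the components are independent. Tail
probabilities come from a Gaussian fitted robustly (median/MAD) to the
empirical S_DR distribution, with Benjamini–Hochberg FDR control. A gene is
called **llc** when q ≤ 0.05, S_DR lies above the fitted center, and the gene
is rhythmic in the old condition; **lost** is the mirror-image call.

**Reports.** Transition categories (highly rhythmic in one age, arrhythmic in
the other; rhythmic in both; ≥ 2 h phase shifters), peak-phase histograms in
the six 4-h sampling bins, and a time-averaged differential-expression
stand-in (all samples of an age treated as replicates; Welch t-test on
log2(x+1); FDR 0.01, fold change ≥ 1.5, FPKM ≥ 1).

## Worked example

The numbered drivers under `analysis/` run a complete demo study on a
simulated 2,000-gene, two-age dataset and write their tables to
`results/demo/`:

```
$ python analysis/01_simulate.py
simulated 2000 genes x 24 samples (seed 42)
...
$ python analysis/02_detect_rhythms.py
young: 536 rhythmic of 2000 genes
old:   533 rhythmic of 2000 genes
$ python analysis/03_differential_rhythmicity.py
1905 genes in the S_DR family, 95 excluded
calls: 62 llc, 51 lost
sensitivity for implanted llc: 0.96 (50 genes)
sensitivity for implanted lost: 1.00 (50 genes)
top 5 by |S_DR|:
             s_DR    q_sdr  call class_label
g01700_lost -5.94  3.4e-10  lost        lost
g01717_lost -5.56 5.35e-09  lost        lost
g01661_llc   4.96 4.12e-07   llc         llc
$ python analysis/04_report.py
transition categories:
                 rhythmic_both: 372
                 phase_shifted: 88
 rhythmic_young_arrhythmic_old: 27
 rhythmic_old_arrhythmic_young: 24
differential expression: 93 up, 0 down (FDR 0.01, FC >= 1.5)
```

The dataset implants 50 de-novo cyclers (rhythmic only in old), 50 rhythm
losers, 100 phase shifters (≥ 2 h), 50 amplitude changers and 100 flat genes
with an age-shifted baseline among 1,650 null genes. 48 of the 50 implanted
de-novo cyclers are recovered as llc calls at FDR 0.05; the extra llc calls
are amplitude-change genes, which genuinely gain rhythmic robustness. The
same pipeline is available as a CLI (`circadiff simulate|detect|sdr|report|run`)
driven by a YAML config, and as plain library functions.

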