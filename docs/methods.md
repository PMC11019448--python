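# Methods

## The corticolimbic index

Alzheimer disease is heterogeneous in *where* neurofibrillary tangles
accumulate: some brains show disproportionate cortical burden with a
relatively spared hippocampus, others the reverse.  The corticolimbic index
(CLix) flattens that two-dimensional pattern into a single continuous score
on [0, 40], built from thioflavin-S tangle counts in five regions — CA1 and
subiculum (posterior hippocampus) and superior temporal, inferior parietal
and middle frontal cortex.

Given a reference distribution for each region and for the
hippocampal:cortical count ratio, a case is scored as

```
hipp_pct  = mean(pct(CA1), pct(subiculum))
cort_pct  = mean(pct(sup_temporal), pct(inf_parietal), pct(mid_frontal))
ratio     = (mean hippocampal count + ε) / (mean cortical count + ε)
ratio_pct = pct(ratio)

Q     = (ratio_pct + hipp_pct + (100 − cort_pct)) / 3
score = 0.4 · Q
```

where `pct(·)` is the mid-rank empirical-CDF percentile
`100·(below + 0.5·equal)/n` against the reference.  Subtypes are binned
half-open: score < 10 → hippocampal sparing, 10 ≤ score < 30 → typical,
score ≥ 30 → limbic predominant (the boundary value 30 is limbic
predominant).

Design choices worth stating, since several were genuinely open:

- **ECDF convention.** Mid-rank, no interpolation.  It is symmetric
  (a value at the median of an odd, distinct reference gets exactly 50),
  tie-robust, and makes the extreme constructions attain exactly 0 and 100.
- **Composite.** An equal-weight mean of the ratio percentile, hippocampal
  percentile and *reversed* cortical percentile, scaled by 0.4.  This is the
  simplest composite with the intended monotone semantics — low score =
  cortical predominance — and it is isolated behind one function with
  configurable weights so an alternative composite can be swapped in.  The
  score is provably monotone: raising any cortical count can only lower it,
  raising any hippocampal count can only raise it (both the compartment
  percentile and the ratio move in the same direction).
- **Pseudocount.** ε = 0.5 in both ratio terms keeps the ratio finite and
  positive for a tangle-free cortex, which genuinely occurs at the
  limbic-predominant extreme.
- **Reference source.** Either cohort-derived (`build_reference`, ≥ 20
  complete cases) or a fixed JSON reference file, so scores can be pinned
  across cohorts.  Percentile scoring depends only on ranks, so the counting
  unit (per field vs per mm²) does not change scores.
- **Missingness.** Rejected at scoring by default; an opt-in flag scores
  from the mean of the available regions per compartment (logged), provided
  each compartment retains at least one region.
- **Precision.** Scores are carried at full float precision and printed at
  one decimal; proportions are rounded half-away-from-zero at the precision
  being printed.

## Cohort screening

The exclusion cascade removes, in order: non-AD primary neuropathologic
diagnosis, neuropathologically normal brains, cases without tangle data,
known AD gene variant carriers, and hippocampal sclerosis.  A multi-flag
case is attributed to the *first* matching rule, so per-rule tallies are
disjoint and conserve `n_input = n_remaining + n_excluded`.  The surviving
set is independent of rule order; only the attribution follows it.

The digital-pathology subgroup takes, per subtype, the n lowest-scoring
eligible hippocampal-sparing cases, the n highest-scoring limbic-predominant
cases, and the n typical cases closest to the cohort median score
("centralized"), after screening out copathologies that confound glial
measurements (meningitis, encephalitis, (micro)infarcts, Lewy body disease).
Ties break on case id, making selection deterministic.

## Synthetic cohorts

Real per-case counts for a brain-bank series of this kind are not publicly
deposited, so the generator plants a known truth and the tests ask whether
the pipeline recovers it.  Each case draws a latent corticolimbic trait
λ ~ Beta(2, 2) (λ→1 = limbic predominant).  Regional counts are negative
binomial (dispersion 1.5 — tangle counts are overdispersed) with log-linear
means `base·exp(slope·(λ−0.5))`; hippocampal slopes are +3, cortical −3,
with baselines (CA1 30, subiculum 24, cortex 8–12 per field) reflecting the
heavier hippocampal burden of end-stage disease.  The slope magnitude was
fixed at design time so the computed score tracks the latent trait at
Spearman ρ > 0.8 under the stated dispersion; at ±3 the realized recovery
is ≈ 0.85 and the cohort splits roughly 17/66/17% across subtypes.

Continuous covariates are coupled to λ through a Gaussian copula: to hit a
Spearman target ρ_s, the normal-score correlation is set to
`2·sin(π·ρ_s/6)`, which controls the rank correlation exactly for any
continuous marginal.  Defaults follow the reported cohort-level effects:
age at onset +0.39, disease duration +0.07, education −0.11, MMSE decline
rate (points lost/y) −0.27, Braak stage −0.18, Thal phase +0.01, Kalaria
scale +0.10, brain weight ~0.  Ordinal marginals (Braak 3–6, Thal 3–5,
Kalaria 0–12, education in whole years) are discretized after coupling,
which attenuates realized correlations slightly (< 0.02 at these
granularities).  Binary covariates use linear probability curves in λ:
atypical syndrome 0.50→0.05 (atypical presentations concentrate at the
hippocampal-sparing end), male sex 0.60→0.35, APOE ε4 0.45→0.75, TREM2
R47H 0.06→0.008 (≈ 3% prevalence), TDP-43 positivity 0.30→0.65.

MMSE series get a noisy baseline near 26, visit gaps around one year, and a
per-case true decline rate (gamma, mean 2.5 points/y) coupled to λ; 15% of
cases have fewer than two visits, so the decline estimate is missing — the
reason the decline variable is excluded from the default forest.

What the generator does *not* emulate: site effects, correlated
region-level measurement error, informative missingness, secular trends in
clinical documentation, or any image-level process.  Passing recovery tests
therefore demonstrates that the pipeline measures what it claims under a
faithful-null cohort, not that real-data confounds are handled.

## Statistics

Rank tests are delegated to scipy behind validated wrappers: Spearman
(mid-rank ties), tie-corrected Kruskal-Wallis (all-identical input returns
H = 0, p = 1), and Wilcoxon rank-sum — exact when the smaller group has ≤ 8
observations and no ties, otherwise the continuity- and tie-corrected
normal approximation (at n = 7 per group the approximation sits within
0.013 of the exact enumeration).  Fisher's exact test reports the
conditional maximum-likelihood odds ratio for 2×2 tables; for 2×K tables
the p-value is a full Freeman–Halton enumeration over tables with the
observed margins (implemented here; cross-checked against R's
`fisher.test`).  The partial Spearman correlation rank-transforms all three
vectors, residualizes the ranks of x and y on the ranks of z by least
squares, and correlates the residuals, with a two-sided t p-value on n − 3
degrees of freedom; a constant covariate falls back to the plain Spearman
with a warning.  MMSE decline is the negated least-squares slope of score
on time (positive = decline), requiring ≥ 2 visits.

No multiple-testing correction is applied by default (α = .05 throughout);
the analysis layer is calibrated — on null simulations each test rejects at
5% ± 2%.

## Variable importance

The forest is a bagged ensemble of 500 regression trees with
`mtry = max(1, p/3)` and minimum leaf size 5, standard regression-forest
practice.  Bootstrap indices are drawn in-package so out-of-bag (OOB)
membership is known exactly.  Importance of variable j is

```
%IncMSE_j = 100 · (mean over repeats of OOB-MSE with column j permuted − OOB-MSE) / OOB-MSE
```

with 50 whole-column permutation repeats by default (a raw-difference
variant is available by flag).  Irrelevant variables land near zero and may
be slightly negative.  Listwise deletion (logged) handles missing
predictors; by default age at death is excluded (collinear with age at
onset) and MMSE decline is excluded (missingness), both re-addable by the
caller.

## Problem sizes and numerical notes

Recovery checks run at n = 2000 cases over 5 seeds with 500-tree forests
and 5 permutation repeats (ranking stabilizes well before 50 repeats);
coupling-fidelity checks use n = 5000; null calibration uses 1000
replicates at n = 100.  Scores are clamped to [0, 40] against float drift;
reference validation enforces sorted, finite, equal-length lists and ≥ 20
cases.  Exact-test enumeration is reserved for small tables/samples where
it is tractable at a desk; the exact-vs-approximate switch is recorded in
the statistic name and sample size of each result.

## Known limitations

- The composite is a documented stand-in with the stated monotone
  semantics; no claim is made that it reproduces published per-case scores,
  whose defining formula and reference percentiles are not deposited.
- The generator's marginals (normal/gamma baselines, probability curves)
  are field-plausible choices, config-exposed, not estimates from data.
- 2×K exact enumeration scales poorly beyond small tables; large tables
  should use the 2×2 collapse or asymptotic alternatives.
- Forest hyperparameters beyond tree count follow common practice and are
  exposed rather than tuned.
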