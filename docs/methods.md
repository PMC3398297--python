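# Methods notes

## The tests

**Brown–Forsythe.** For hard calls g ∈ {0,1,2} the test is a one-way ANOVA
on Z_i = |y_i − med(y | g_i)|, the absolute deviation from the
genotype-group *median* (the median-centered variant is robust to skewed
traits, unlike mean-centered Levene). The statistic T² is referred to
F(k−1, N−k); for large N this is indistinguishable from χ²_{k−1}/(k−1)
(asserted to 1e−3 at N = 10⁴ in the tests). Group medians for even group
sizes are the midpoint of the two central order statistics. Missing data
are removed pairwise over (y, g).

**SVLM.** Stage 1: OLS of y on [1, d, X]; stage 2: OLS of the squared
stage-1 residuals on [1, d]. Inference in both stages is the classical
homoskedastic t-test, two-sided, with df = n − 2 − ncol(X) (stage 1) and
n − 2 (stage 2). The stage-2 response r² is heteroskedastic by
construction whenever variance heterogeneity is present, so the classical
SE is a simplification; it is what keeps the null calibration results
below reproducible, and an HC0 sandwich alternative is available behind
`robust_se=True` (off by default). Covariates are excluded from stage 2 by
default — the squared residuals are already mean-adjusted for them — and
can be carried over with `stage2_covariates=True`. Both choices were left
open by the method's description; the defaults are the simplest reading of
"regression on the squared residuals using the SNP as the predictor".

Assumptions worth keeping in mind: stage 1 assumes the mean model is
linear in the dosage (additive allele effect); the stage-2 t-test assumes
the squared residuals are well-behaved enough for CLT-based inference,
which is why heavy-tailed (skewed-error) traits erode SVLM's power faster
than Levene's (the test suite demonstrates the power reversal under
χ²_{df=1} errors).

## Degenerate inputs and numerical choices

* Monomorphic SNP (one genotype group / constant dosage) →
  `MonomorphicError`; undefined statistic (all deviations equal within
  every group, or fewer than two groups with ≥ 2 observations) →
  `UndefinedStatisticError`. The two are distinct so a scan can distinguish
  "nothing to test" from "degenerate data"; `run_scan` converts them to the
  record statuses `monomorphic` / `undefined` instead of aborting.
* Squared residuals constant to machine precision (e.g. a two-point trait
  with a binary dosage) would otherwise produce a 0/0 t-statistic from
  floating-point noise; this is detected (relative spread ≤ 1e−10) and
  reported as slope 0, p = 1.
* `hard_call`: doses round to the nearest integer in {0,1,2}; a dose
  exactly midway (x.5) rounds **up**, and a distance exactly equal to
  `max_distance` is **kept** (≤ comparison). Deterministic and documented
  rather than banker's rounding.
* Listwise deletion per SNP over (y, d/g, X); covariate columns that are
  constant after deletion are dropped with a warning.
* Scans flag `low_group_count` when the smallest hard-called genotype
  group among analyzed samples is below 80 — the regime where SVLM's type
  I error turns conservative (see the acceptance checks at 10 and 100
  heterozygotes). Statistics are still reported.

## The trait simulator

`simulate_trait` draws y = μ + β_g·g + β_F·F + β_gF·g·F + ε with
g ~ Binomial(2, P_B) (Hardy–Weinberg), F ~ N(μ_F, σ_F²), and ε either
standard normal or χ²_df centered and scaled to unit variance
(`standardize=True` default; type I error is scale-invariant, and unit
error variance keeps power comparisons across families at matched
signal-to-noise). Defaults μ = μ_F = 0, σ_F² = 1, P_B = 0.4 — the
canonical simulation conditions for these tests. Conditional on g the
trait variance is (β_F + β_gF·g)²σ_F² + Var(ε), so β_gF ≠ 0 produces
genotypic variance heterogeneity and β_F = β_gF = 0 is the homogeneous
null.

`simulate_genotypes(mode="fixed_counts")` places exactly round(2·n·P_B)
heterozygotes (rest homozygous major). It exists for the extreme-frequency
experiments, where a frequency like 0.0005 in n = 10,000 is identified
with exactly 10 carriers; binomial draws at such frequencies would often
be monomorphic and would make "type I error at 10 heterozygotes" a
moving target.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, genotype uncertainty/imputation error in the dosages it feeds to
SVLM, covariate confounding, pedigree/polygenic correlation structure, and
non-Gaussian interacting factors. Passing calibration tests therefore show
correctness of the statistics under clean HWE sampling with independent
errors — not robustness to stratification or relatedness, which callers
should handle upstream (e.g. by pre-adjusting the trait with a mixed
model and scanning the residuals).

## Experiments

`type1_error` / `power` run n_replicates independent replicates (fresh
genotypes and trait each time), apply the chosen test, and return the
rejection fraction at p ≤ α with its binomial SE. Replicates on which the
test is degenerate are excluded from the denominator and counted in
`n_skipped` — a skipped test cannot reject. Replicate r of an experiment
with seed s uses the RNG substream `SeedSequence((s, r))`, so any single
replicate is reproducible in isolation and results are independent of
batch size. The drivers use vectorized closed-form kernels (rows =
replicates); the test suite pins kernel outputs to the scalar
`svlm_test`/`brown_forsythe_levene` APIs to 1e−15-ish agreement.

**Optimal factor effect.** Power to detect an interaction β_gF is not
monotone in the factor's main effect β_F; `optimal_factor_effect` returns
the β_F maximizing an analytic proxy for the SVLM stage-2 noncentrality:
slope(v(g) on g)² / Var(r²), with v(g) = (β_F + β_gF·g)²σ_F² + σ_ε² and
the genotype distribution Binomial(2, P_B). Var(r²) is evaluated with
Gaussian fourth moments for both F and ε, so with σ_F² = σ_ε² = 1 the
optimum depends on β_gF alone — the convention that keeps power curves
across error families at matched settings (each family getting its own
error-kurtosis-dependent optimum would confound the family comparison).
The arg-max is taken over a dense grid (default β_F ∈ [−3, 3], step
0.001), ties broken toward smaller |β_F|; the tests check the closed-form
moments against independent Gauss–Hermite quadrature and the arg-max
against brute force. A simulation-based maximizer was deliberately not
used: the proxy is deterministic and testable.

**Problem sizes.** The acceptance script runs every scenario at full
scale: 20,000 replicates of n = 10,000 (the vectorized kernels make this
~90 s total on one core). The pytest acceptance checks use
5,000-replicate runs (tolerance three combined binomial SEs) and
1,000-replicate power points at n = 10,000 — sizes at which every
assertion's Monte-Carlo margin is several times its SE. The power checks
use the β_gF grid (0.02, 0.04, 0.06, 0.08): at n = 10,000 with optimal
β_F both tests saturate near power 1 above β_gF ≈ 0.1, so the informative
(strictly increasing, order-separating) region lies below that.

## File formats

* Text dosage dialect: header `SNP A1 A2 <sample ids...>`,
  whitespace-delimited, one SNP per row, doses in [0, 2], `NA` missing,
  gzip by `.gz` suffix. A1 is the effect allele. Doses are written at 6
  decimals, and read→write round-trips are byte-identical at that
  precision.
* VCF: per-sample DS preferred, else dose = P(het) + 2·P(hom-alt) from
  GP; effect allele = ALT; multi-allelic records and records with neither
  field are skipped with warnings. FORMAT floats are single-precision, so
  doses are rounded to 6 decimals at read — this makes hand-computed
  GP→dose values exact and is far below any meaningful dosage resolution.
* Results TSV: one row per SNP in input order, both analysis stages plus
  QC fields, `NA` for missing, p-values in 6-digit scientific notation.

## Known limitations

* No pedigree / mixed-model adjustment, no binary traits, no exact
  small-sample permutation p-values.
* The stage-2 classical SE is anti-conservative in principle under strong
  heterogeneity; for discovery screens this matters little (the null is
  what calibration protects), but effect CIs from stage 2 should be
  treated as approximate — or re-run with `robust_se=True`.
* BGEN/PLINK binary dosages and chunked/out-of-core execution are out of
  scope; inputs are held in memory.
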