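# vqtlscan

Genome-wide variance-heterogeneity scanning for quantitative traits.

A SNP that interacts with other loci or with environmental factors leaves a
signature even when the partners are unmeasured: the *variance* of the trait
differs between genotype groups. Testing every SNP for such variance
heterogeneity (a "vQTL" scan) costs one test per SNP — the same as an
ordinary GWAS — yet flags candidate interacting loci regardless of how many
partners are involved. `vqtlscan` implements the two standard tests:

* **Brown–Forsythe / Levene test** for hard genotype calls g ∈ {0, 1, 2}.
  With Z_i = |y_i − med(y | g_i)| the deviation of each trait value from
  its genotype-group median,

      T² = (N − k) Σ_j n_j (Z̄_j − Z̄)² / [ (k − 1) Σ_i (Z_i − Z̄_{g_i})² ],

  referred to F(k−1, N−k), where k ≤ 3 is the number of observed genotype
  groups and n_j their sizes.

* **SVLM** (squared residual value linear modeling) for imputed allele
  dosages d ∈ [0, 2]. Stage 1 fits y ~ 1 + d + covariates by OLS; stage 2
  regresses the squared stage-1 residuals r² on 1 + d and reports the
  two-sided t-test of the dosage slope. Since Var(Y|g) = E[r²|g], a dosage
  effect on the squared-residual mean *is* a dosage effect on the
  conditional variance — and because both stages are ordinary regressions,
  fractional (imputed) genotypes and covariates come for free, and per-SNP
  effect/SE pairs can be meta-analyzed across cohorts like any GWAS result.

The package also ships the Monte-Carlo machinery used to characterize both
tests: a trait simulator

    y_i = μ + β_g·g_i + β_F·F_i + β_gF·g_i·F_i + ε_i,
    g_i ~ Binomial(2, P_B),  F_i ~ N(μ_F, σ_F²),  ε_i Gaussian or
    standardized χ² (df = 1 or 5),

type I error / power experiment drivers, and an analytic rule for the
"optimal" factor main effect β_F that maximizes power to detect a given
interaction β_gF.

## Worked example

A 5-SNP × 2,000-sample toy cohort in the text dosage dialect
(`SNP A1 A2 <sample ids...>`, one SNP per row, doses in [0, 2], `NA`
missing), where `rs3` interacts with an unmeasured Gaussian factor
(β_F = 0.7, β_gF = 0.4) and the other four SNPs are null:

```sh
vqtlscan scan --dosages toy.dose.txt --pheno toy.pheno.tsv \
              --pheno-col height --test svlm --out toy.scan.tsv
```

```
snp_id  effect_allele  n_used  eaf      mean_beta   mean_p        var_beta   var_p         test_used  status
rs0     A              2000    0.301     0.0209447  6.562679e-01  0.0868231  3.752273e-01  svlm       ok
rs1     A              2000    0.29875   0.0178586  7.050154e-01  0.166713   8.938680e-02  svlm       ok
rs2     A              2000    0.2845    0.0184725  7.062101e-01  0.0757522  4.575639e-01  svlm       ok
rs3     A              2000    0.299    -0.0772687  1.058881e-01  0.832617   2.738337e-17  svlm       ok
rs4     A              2000    0.3085    0.0416402  3.791634e-01  0.114675   2.447602e-01  svlm       ok
```

(`mean_se`/`var_se` columns elided here.) Each row reports both analysis
stages: `mean_*` is the ordinary association of the trait mean with the
dosage (stage 1 — so the scan doubles as a regular GWAS), `var_*` the
variance-heterogeneity test (stage 2). The interacting SNP rs3 stands out
at `var_p` ≈ 3·10⁻¹⁷ with no mean effect (`mean_p` = 0.11), exactly the
signature a mean-only GWAS misses; the four null SNPs sit at `var_p` > 0.05.
Its `var_beta` ≈ 0.83 estimates the increase in conditional trait variance
per effect allele. No multiple-testing correction is applied — raw p-values
are emitted and genome-wide thresholds are the user's choice.

`--vcf file.vcf` replaces `--dosages` for imputed data: the dose is the DS
FORMAT field when present, otherwise P(het) + 2·P(hom-alt) from GP;
`--test levene` converts doses to hard calls first (calls farther than
`--max-distance` from an integer become missing).

Simulation experiments run from presets or key=value config files:

```sh
vqtlscan simulate --preset type1-normal --replicates 2000 --seed 7 --out type1.tsv
```

```
test   n      p_B  beta_g  beta_F  beta_gF  error_family  df  n_replicates  rate   se        n_skipped  seed
svlm   10000  0.4  0.0     0.0     0.0      normal        NA  2000          0.057  0.005184  0          7
```

i.e. an empirical type I error of 0.057 ± 0.005 at the nominal 0.05
threshold from 2,000 null replicates of n = 10,000. Presets:
`type1-normal`, `type1-chisq5`, `type1-chisq1`, `type1-lowfreq`
(heterozygote counts 10–100 in n = 10,000, both tests), `power-grid`
(power along a β_gF grid at the optimal β_F, both tests).

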