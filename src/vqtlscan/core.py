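"""Variance-heterogeneity (vQTL) testing for quantitative traits.

A locus whose genotype is associated with the *variance* of a quantitative
trait — not only its mean — is a candidate for interaction with unmeasured
genetic or environmental factors: if allele B interacts with some factor F,
the trait spread grows with the number of B alleles a carrier holds.
Scanning the genome for such variance heterogeneity is a single-SNP-cost
screen for interactions, no matter how many partners are involved.

Two tests are implemented:

* the Brown–Forsythe variant of Levene's test for hard genotype calls
  (one-way ANOVA on absolute deviations from the genotype-group median,
  referred to F(k-1, N-k)), and

* SVLM (squared residual value linear modeling) for imputed allele
  dosages: stage 1 regresses the trait on dosage and covariates by OLS;
  stage 2 regresses the squared stage-1 residuals on dosage and tests the
  slope.  Because Var(Y|g) = E[(Y - E[Y|g])^2 | g], a dosage effect on the
  squared residual mean is a dosage effect on the conditional variance,
  and the machinery is plain regression, so imputed (fractional) genotypes
  pose no problem.

The module is organised in the order a study runs:

1.  errors, domain containers;
2.  the per-SNP tests (``brown_forsythe_levene``, ``svlm_test``,
    ``hard_call``) and their vectorized batch kernels;
3.  the trait simulator (y = mu + beta_g*g + beta_F*F + beta_gF*g*F + eps
    with g ~ Binomial(2, P_B), F Gaussian, eps Gaussian or standardized
    chi-square) and the type I error / power experiment drivers;
4.  genome-wide scan I/O: text dosage matrices, VCF DS/GP dosages, the
    scan loop, and result tables.
"""

from __future__ import annotations

import gzip
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("vqtlscan")

__all__ = [
    "MonomorphicError",
    "UndefinedStatisticError",
    "RankDeficiencyError",
    "ConfigError",
    "LeveneResult",
    "SvlmResult",
    "brown_forsythe_levene",
    "svlm_test",
    "hard_call",
    "ErrorSpec",
    "SimulationModel",
    "ExperimentConfig",
    "RateEstimate",
    "simulate_genotypes",
    "simulate_trait",
    "replicate_rng",
    "type1_error",
    "power",
    "svlm_power_proxy",
    "optimal_factor_effect",
    "power_curve",
    "read_experiment_config",
    "write_experiment_results",
    "EXPERIMENT_COLUMNS",
    "DosageMatrix",
    "ScanRecord",
    "read_dosage_table",
    "write_dosage_table",
    "read_vcf_dosages",
    "run_scan",
    "write_results",
    "read_results",
]

# Smallest genotype-group count below which SVLM starts running conservative;
# scans flag (but still report) SNPs under this count.
LOW_GROUP_COUNT = 80


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class VqtlError(ValueError):
    """Base class for all vqtlscan-specific errors."""


class MonomorphicError(VqtlError):
    """The SNP carries no genotype/dosage variation in the analyzed samples."""


class UndefinedStatisticError(VqtlError):
    """The test statistic is undefined (degenerate denominator or groups)."""


class RankDeficiencyError(VqtlError):
    """Too few complete observations for the number of fitted parameters."""


class ConfigError(VqtlError):
    """An experiment or run configuration violates its preconditions."""


# ---------------------------------------------------------------------------
# Per-SNP test results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeveneResult:
    """Brown–Forsythe test outcome for one SNP.

    ``group_sizes`` and ``group_medians`` are reported per genotype
    (0, 1, 2 copies of the effect allele); absent genotype classes have
    size 0 and median NaN.
    """

    statistic: float
    df1: int
    df2: int
    p_value: float
    group_sizes: tuple[int, int, int]
    group_medians: tuple[float, float, float]


@dataclass(frozen=True)
class SvlmResult:
    """Two-stage SVLM outcome for one SNP.

    Stage 1 models the trait mean (beta in trait units per allele); stage 2
    models the squared stage-1 residuals (beta in squared-trait units per
    allele) — its slope p-value is the variance-heterogeneity test.
    """

    stage1_beta: float
    stage1_se: float
    stage1_p: float
    stage2_beta: float
    stage2_se: float
    stage2_p: float
    n_used: int


# ---------------------------------------------------------------------------
# Input coercion helpers
# ---------------------------------------------------------------------------


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _covariate_array(X, n: int) -> np.ndarray:
    """Coerce covariates to an (n, p) float array; None/empty -> (n, 0)."""
    if X is None:
        return np.empty((n, 0))
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError(f"covariate rows ({X.shape[0]}) do not match samples ({n})")
    return X


def _drop_constant_columns(X: np.ndarray) -> np.ndarray:
    if X.shape[1] == 0:
        return X
    keep = np.ptp(X, axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} constant covariate column(s) "
            "after restriction to analyzed samples",
            UserWarning,
            stacklevel=3,
        )
    return X[:, keep]


# ---------------------------------------------------------------------------
# Brown–Forsythe / Levene test (hard genotype calls)
# ---------------------------------------------------------------------------


def brown_forsythe_levene(y, g) -> LeveneResult:
    """Brown–Forsythe variance-homogeneity test across genotype groups.

    For each individual i with genotype g_i, the absolute deviation from the
    genotype-group *median* is Z_i = |y_i - med(y | g_i)|.  The statistic is
    the one-way ANOVA F on the Z values,

        T^2 = (N - k) * sum_j n_j (Zbar_j - Zbar)^2
              / [ (k - 1) * sum_i (Z_i - Zbar_{g_i})^2 ],

    referred to F(k-1, N-k), where k is the number of observed genotype
    groups and n_j their sizes.  Missing entries in either vector are
    removed pairwise.

    Parameters
    ----------
    y : array-like of float
        Trait values; NaN marks a missing observation.
    g : array-like
        Genotype calls in {0, 1, 2}; NaN marks missing.

    Raises
    ------
    MonomorphicError
        Fewer than two observed genotype groups.
    UndefinedStatisticError
        Fewer than two groups with at least two observations, or all
        deviations equal within every group (zero denominator).
    """
    y = _as_float_vector(y, "y")
    g = _as_float_vector(g, "g")
    if y.shape != g.shape:
        raise ValueError("y and g must have equal length")
    mask = np.isfinite(y) & np.isfinite(g)
    y, g = y[mask], g[mask]
    if y.size < 2:
        raise MonomorphicError("fewer than 2 observed samples")
    gi = g.astype(np.int64)
    if np.any(gi != g) or gi.min(initial=0) < 0 or gi.max(initial=0) > 2:
        raise ValueError("genotype calls must be integers in {0, 1, 2}")

    sizes = np.bincount(gi, minlength=3)
    present = np.flatnonzero(sizes)
    k = present.size
    if k < 2:
        raise MonomorphicError("fewer than 2 genotype groups observed")
    if np.count_nonzero(sizes >= 2) < 2:
        raise UndefinedStatisticError(
            "need at least 2 genotype groups with >=2 observations"
        )

    n = y.size
    medians = np.full(3, np.nan)
    for j in present:
        medians[j] = np.median(y[gi == j])
    z = np.abs(y - medians[gi])
    zbar = z.mean()
    num = 0.0
    den = 0.0
    for j in present:
        zj = z[gi == j]
        num += zj.size * (zj.mean() - zbar) ** 2
        den += ((zj - zj.mean()) ** 2).sum()
    if den == 0.0:
        raise UndefinedStatisticError(
            "all absolute deviations equal within every genotype group"
        )
    df1, df2 = k - 1, n - k
    t2 = df2 * num / (df1 * den)
    p = float(stats.f.sf(t2, df1, df2))
    return LeveneResult(
        statistic=float(t2),
        df1=df1,
        df2=df2,
        p_value=p,
        group_sizes=tuple(int(s) for s in sizes),
        group_medians=tuple(float(m) for m in medians),
    )


# ---------------------------------------------------------------------------
# OLS primitives shared by SVLM stages and the scan mean model
# ---------------------------------------------------------------------------


def _ols_fit(A: np.ndarray, y: np.ndarray, robust: bool = False):
    """Least-squares fit y ~ A. Returns (beta, se, df, residuals).

    Classical (homoskedastic) standard errors by default; HC0 sandwich
    errors when ``robust``.
    """
    n, p = A.shape
    if n <= p:
        raise RankDeficiencyError(
            f"{n} complete observations for {p} parameters"
        )
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p:
        raise RankDeficiencyError("design matrix is rank deficient")
    resid = y - A @ beta
    df = n - p
    ata_inv = np.linalg.inv(A.T @ A)
    if robust:
        meat = (A * resid[:, None] ** 2).T @ A
        cov = ata_inv @ meat @ ata_inv
    else:
        s2 = float(resid @ resid) / df
        cov = s2 * ata_inv
    se = np.sqrt(np.diag(cov))
    return beta, se, df, resid


def svlm_test(
    y,
    d,
    X=None,
    *,
    robust_se: bool = False,
    stage2_covariates: bool = False,
) -> SvlmResult:
    """Two-stage SVLM variance-heterogeneity test on an allele dosage.

    Stage 1 fits ``y ~ intercept + d + X`` by ordinary least squares and
    takes residuals r; stage 2 fits ``r^2 ~ intercept + d`` and reports the
    two-sided t-test of the dosage slope.  Under homogeneous genotypic
    variance the stage-2 slope is zero; trait variance rising (falling)
    with the dosage shows up as a positive (negative) slope.

    Parameters
    ----------
    y : array-like of float
        Trait values, NaN = missing.
    d : array-like of float
        Allele dosage in [0, 2] (expected effect-allele count), NaN = missing.
    X : array-like or DataFrame, optional
        Covariates for the stage-1 mean model.  Constant columns (after
        listwise deletion) are dropped with a warning.
    robust_se : bool
        Use HC0 sandwich standard errors in both stages instead of the
        classical homoskedastic ones.
    stage2_covariates : bool
        Also carry the covariates into the stage-2 design (default carries
        only the intercept and the dosage).

    Raises
    ------
    MonomorphicError
        Dosage constant in the analyzed samples.
    RankDeficiencyError
        Too few complete observations for the parameters fitted.
    """
    y = _as_float_vector(y, "y")
    d = _as_float_vector(d, "d")
    if y.shape != d.shape:
        raise ValueError("y and d must have equal length")
    X = _covariate_array(X, y.size)
    with np.errstate(invalid="ignore"):
        if np.nanmin(d) < 0 or np.nanmax(d) > 2:
            raise ValueError("dosages must lie in [0, 2]")

    mask = np.isfinite(y) & np.isfinite(d)
    if X.shape[1]:
        mask &= np.isfinite(X).all(axis=1)
    y, d, X = y[mask], d[mask], X[mask]
    n = y.size
    if n < 3:
        raise RankDeficiencyError("need at least 3 complete observations")
    if np.ptp(d) == 0:
        raise MonomorphicError("dosage is constant in the analyzed samples")
    X = _drop_constant_columns(X)
    if X.shape[1] >= n:
        raise RankDeficiencyError("more covariates than analyzed samples")

    ones = np.ones(n)
    A1 = np.column_stack([ones, d, X])
    b1, se1, df1, resid = _ols_fit(A1, y, robust=robust_se)
    t1 = b1[1] / se1[1]
    p1 = 2.0 * float(stats.t.sf(abs(t1), df1))

    z = resid * resid
    if np.ptp(z) <= 1e-10 * max(float(np.max(np.abs(z))), 1e-300):
        # squared residuals constant to machine precision: no variance signal
        beta2, sse2, p2 = 0.0, 0.0, 1.0
        return SvlmResult(
            stage1_beta=float(b1[1]),
            stage1_se=float(se1[1]),
            stage1_p=p1,
            stage2_beta=beta2,
            stage2_se=sse2,
            stage2_p=p2,
            n_used=n,
        )
    A2 = np.column_stack([ones, d, X]) if stage2_covariates else np.column_stack([ones, d])
    b2, se2, df2, _ = _ols_fit(A2, z, robust=robust_se)
    t2 = b2[1] / se2[1]
    p2 = 2.0 * float(stats.t.sf(abs(t2), df2))

    return SvlmResult(
        stage1_beta=float(b1[1]),
        stage1_se=float(se1[1]),
        stage1_p=p1,
        stage2_beta=float(b2[1]),
        stage2_se=float(se2[1]),
        stage2_p=p2,
        n_used=n,
    )


def hard_call(d, max_distance: float = 0.5) -> np.ndarray:
    """Convert dosages to hard genotype calls in {0, 1, 2}.

    Each dose is rounded to the nearest integer; a dose exactly midway
    (x.5) rounds up.  Calls farther than ``max_distance`` from the dose are
    set missing (NaN); a distance exactly equal to ``max_distance`` is
    kept.  ``max_distance`` must lie in [0, 0.5], so every call is uniquely
    determined.
    """
    if not 0.0 <= max_distance <= 0.5:
        raise ValueError("max_distance must lie in [0, 0.5]")
    d = _as_float_vector(d, "d")
    with np.errstate(invalid="ignore"):
        if np.nanmin(d) < 0 or np.nanmax(d) > 2:
            raise ValueError("dosages must lie in [0, 2]")
    calls = np.minimum(np.floor(d + 0.5), 2.0)  # x.5 rounds up; 2.0 stays 2
    calls[np.abs(d - calls) > max_distance] = np.nan
    calls[~np.isfinite(d)] = np.nan
    return calls


# ---------------------------------------------------------------------------
# Vectorized batch kernels (replicate matrices, rows = replicates)
#
# These are the closed-form no-covariate fast paths used by the simulation
# drivers and tested against the scalar APIs above.
# ---------------------------------------------------------------------------


def _svlm_batch_pvalues(Y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Stage-2 SVLM p-value per row of (Y, G); NaN for monomorphic rows."""
    n = Y.shape[1]
    gc = G - G.mean(axis=1, keepdims=True)
    sgg = np.einsum("ij,ij->i", gc, gc)
    ok = sgg > 0
    sgg_safe = np.where(ok, sgg, 1.0)

    b1 = np.einsum("ij,ij->i", gc, Y) / sgg_safe
    r = Y - Y.mean(axis=1, keepdims=True) - b1[:, None] * gc
    z = r * r
    b2 = np.einsum("ij,ij->i", gc, z) / sgg_safe
    e = z - z.mean(axis=1, keepdims=True) - b2[:, None] * gc
    s2 = np.einsum("ij,ij->i", e, e) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = b2 / np.sqrt(s2 / sgg_safe)
    p = 2.0 * stats.t.sf(np.abs(tval), n - 2)
    p[~ok] = np.nan
    return p


def _levene_batch_pvalues(Y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Brown–Forsythe p-value per row of (Y, G); NaN for degenerate rows.

    Degenerate rows are those with fewer than two genotype groups of size
    >=2, or with zero within-group deviation sum — mirroring the scalar
    error contract.
    """
    nb, n = Y.shape
    gi = G.astype(np.int64)
    med = np.full((nb, 3), np.nan)
    cnt = np.zeros((nb, 3), dtype=np.int64)
    for j in range(3):
        mask = gi == j
        cj = mask.sum(axis=1)
        cnt[:, j] = cj
        rows = np.flatnonzero(cj)
        if rows.size:
            yj = np.where(mask[rows], Y[rows], np.nan)
            med[rows, j] = np.nanmedian(yj, axis=1)

    medg = np.take_along_axis(med, gi, axis=1)
    z = np.abs(Y - medg)
    zbar = z.mean(axis=1)
    num = np.zeros(nb)
    den = np.zeros(nb)
    for j in range(3):
        mask = gi == j
        cj = cnt[:, j]
        zsum = np.where(mask, z, 0.0).sum(axis=1)
        zbj = np.where(cj > 0, zsum / np.maximum(cj, 1), 0.0)
        num += np.where(cj > 0, cj * (zbj - zbar) ** 2, 0.0)
        den += np.where(mask, (z - zbj[:, None]) ** 2, 0.0).sum(axis=1)

    k = (cnt > 0).sum(axis=1)
    ok = ((cnt >= 2).sum(axis=1) >= 2) & (den > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = (n - k) * num / ((k - 1) * den)
    p = stats.f.sf(t2, np.maximum(k - 1, 1), n - k)
    p = np.asarray(p, dtype=float)
    p[~ok] = np.nan
    return p


# ---------------------------------------------------------------------------
# Trait simulation: y = mu + beta_g*g + beta_F*F + beta_gF*g*F + eps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorSpec:
    """Residual-error distribution for the trait simulator.

    family='normal' draws eps ~ N(0, 1).  family='chisq' draws a
    chi-square with ``df`` degrees of freedom; with ``standardize`` (the
    default) it is centered and scaled to mean 0, variance 1:
    eps = (chi2_df - df) / sqrt(2 df).  Type I error of both tests is
    invariant to the error scale, so standardization only matters for
    power comparisons across families.
    """

    family: str = "normal"
    df: int = 1
    standardize: bool = True

    def __post_init__(self):
        if self.family not in ("normal", "chisq"):
            raise ConfigError(f"unknown error family {self.family!r}")
        if self.family == "chisq" and self.df < 1:
            raise ConfigError("chisq error needs df >= 1")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "normal":
            return rng.standard_normal(n)
        x = rng.chisquare(self.df, n)
        if self.standardize:
            return (x - self.df) / math.sqrt(2 * self.df)
        return x

    def variance(self) -> float:
        if self.family == "normal" or self.standardize:
            return 1.0
        return 2.0 * self.df



@dataclass(frozen=True)
class SimulationModel:
    """Parameter bundle for the interaction trait model.

    y_i = mu + beta_g*g_i + beta_F*F_i + beta_gF*g_i*F_i + eps_i with
    g_i ~ Binomial(2, p_b), F_i ~ N(mu_F, sigma2_F), eps_i from ``error``;
    g, F and eps mutually independent.  The defaults mu = mu_F = 0 and
    sigma2_F = 1 lose no generality for either type I error or power.
    """

    p_b: float = 0.4
    mu: float = 0.0
    beta_g: float = 0.0
    beta_F: float = 0.0
    beta_gF: float = 0.0
    mu_F: float = 0.0
    sigma2_F: float = 1.0
    error: ErrorSpec = field(default_factory=ErrorSpec)

    def __post_init__(self):
        if not 0.0 <= self.p_b <= 1.0:
            raise ConfigError("p_b must lie in [0, 1]")
        if self.sigma2_F <= 0:
            raise ConfigError("sigma2_F must be positive")


def simulate_genotypes(
    n: int,
    p_b: float,
    mode: str = "binomial",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw a genotype vector of length n for effect-allele frequency p_b.

    mode='binomial' draws i.i.d. Binomial(2, p_b) counts (Hardy–Weinberg).
    mode='fixed_counts' places exactly round(2*n*p_b) heterozygotes and
    makes the remainder homozygous major — the construction used for
    extreme-frequency experiments where a frequency is identified with an
    exact heterozygote count (e.g. p_b = 0.0005 in n = 10000 means 10
    carriers) and a binomial draw would often be monomorphic.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if not 0.0 <= p_b <= 1.0:
        raise ConfigError("p_b must lie in [0, 1]")
    if mode == "binomial":
        rng = np.random.default_rng(rng)
        return rng.binomial(2, p_b, size=n).astype(np.int64)
    if mode == "fixed_counts":
        n_het = int(round(2 * n * p_b))
        if n_het > n:
            raise ConfigError("fixed_counts requires 2*n*p_b <= n")
        g = np.zeros(n, dtype=np.int64)
        g[:n_het] = 1
        return g
    raise ConfigError(f"unknown genotype mode {mode!r}")


def simulate_trait(
    model: SimulationModel,
    g,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate one trait vector given genotypes under the interaction model.

    Conditional on g, the trait variance is
    (beta_F + beta_gF*g)^2 * sigma2_F + Var(eps), so any nonzero beta_gF
    (with suitable beta_F) produces genotypic variance heterogeneity while
    beta_F = beta_gF = 0 gives the homogeneous null.
    """
    g = np.asarray(g, dtype=float)
    if not np.isfinite(g).all():
        raise ValueError("genotypes must be complete (no missing entries)")
    rng = np.random.default_rng(rng)
    n = g.size
    f = model.mu_F + math.sqrt(model.sigma2_F) * rng.standard_normal(n)
    eps = model.error.draw(rng, n)
    return model.mu + model.beta_g * g + model.beta_F * f + model.beta_gF * g * f + eps


@dataclass(frozen=True)
class ExperimentConfig:
    """One Monte-Carlo experiment: a model, a test, and replication settings."""

    model: SimulationModel
    n_replicates: int
    seed: int
    n_samples: int = 10_000
    alpha: float = 0.05
    test: str = "svlm"
    genotype_mode: str = "binomial"

    def __post_init__(self):
        if self.n_samples < 10:
            raise ConfigError("n_samples must be >= 10")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError("alpha must lie in (0, 1]")
        if self.test not in ("svlm", "levene"):
            raise ConfigError(f"unknown test {self.test!r}")
        if self.genotype_mode not in ("binomial", "fixed_counts"):
            raise ConfigError(f"unknown genotype mode {self.genotype_mode!r}")


@dataclass(frozen=True)
class RateEstimate:
    """A rejection-rate estimate with its binomial standard error.

    ``n_replicates`` counts the replicates that actually produced a
    p-value; replicates on which the test was degenerate (monomorphic or
    undefined) are excluded from the denominator and reported in
    ``n_skipped`` — a skipped test cannot reject.
    """

    rate: float
    se: float
    n_replicates: int
    n_skipped: int


def replicate_rng(seed: int, r: int) -> np.random.Generator:
    """Independent RNG substream for replicate ``r`` of experiment ``seed``.

    The substream is ``SeedSequence((seed, r))``, so any single replicate
    can be regenerated in isolation.
    """
    return np.random.default_rng(np.random.SeedSequence((seed, r)))


_BATCH_ROWS = 200  # replicate rows simulated per vectorized kernel call


def _rejection_rate(config: ExperimentConfig) -> RateEstimate:
    model = config.model
    n = config.n_samples
    kernel = _svlm_batch_pvalues if config.test == "svlm" else _levene_batch_pvalues
    fixed_g = None
    if config.genotype_mode == "fixed_counts":
        fixed_g = simulate_genotypes(n, model.p_b, "fixed_counts").astype(float)

    n_reject = 0
    n_tested = 0
    n_skipped = 0
    done = 0
    while done < config.n_replicates:
        b = min(_BATCH_ROWS, config.n_replicates - done)
        G = np.empty((b, n))
        Y = np.empty((b, n))
        for i in range(b):
            rng = replicate_rng(config.seed, done + i)
            if fixed_g is None:
                g = rng.binomial(2, model.p_b, size=n).astype(float)
            else:
                g = fixed_g
            G[i] = g
            Y[i] = simulate_trait(model, g, rng)
        p = kernel(Y, G)
        finite = np.isfinite(p)
        n_skipped += int((~finite).sum())
        n_tested += int(finite.sum())
        n_reject += int((p[finite] <= config.alpha).sum())
        done += b

    if n_tested == 0:
        raise UndefinedStatisticError("every replicate was degenerate")
    rate = n_reject / n_tested
    se = math.sqrt(rate * (1.0 - rate) / n_tested)
    return RateEstimate(rate=rate, se=se, n_replicates=n_tested, n_skipped=n_skipped)


def type1_error(config: ExperimentConfig) -> RateEstimate:
    """Empirical type I error: rejection rate under the homogeneous null.

    Requires beta_F = beta_gF = 0 in the model (the null of no variance
    heterogeneity); each replicate draws fresh genotypes (unless
    fixed_counts) and a fresh trait, applies the configured test, and the
    fraction of p-values <= alpha among non-degenerate replicates is
    returned.
    """
    if config.model.beta_F != 0.0 or config.model.beta_gF != 0.0:
        raise ConfigError(
            "type I error experiments require beta_F = beta_gF = 0"
        )
    return _rejection_rate(config)


def power(config: ExperimentConfig) -> RateEstimate:
    """Empirical power: rejection rate under the configured model.

    Same replication machinery as :func:`type1_error` without the
    null-parameter restriction; with beta_gF = 0 it reduces to a type I
    error estimate.
    """
    return _rejection_rate(config)


# ---------------------------------------------------------------------------
# Optimal factor effect (analytic SVLM power proxy)
# ---------------------------------------------------------------------------


def svlm_power_proxy(beta_F, beta_gF: float, model_base: SimulationModel) -> np.ndarray:
    """Noncentrality surrogate for SVLM stage-2 power, as a function of beta_F.

    Let v(g) = (beta_F + beta_gF*g)^2 * sigma2_F + Var(eps) be the
    conditional trait variance and z the squared stage-1 population
    residual (E[z|g] = v(g)).  The proxy is

        slope(v on g over Binomial(2, p_b))^2 / Var(z),

    i.e. the squared population regression slope of the conditional
    variance on the genotype, scaled by the total variance of the squared
    residual.  The stage-2 t statistic concentrates around
    sqrt(n * Var(g) * proxy), so for fixed beta_gF the proxy orders
    beta_F values as asymptotic power does.  Var(z) is evaluated with
    Gaussian fourth moments for both F and the error, so the proxy — and
    hence the optimal beta_F — depends on the error distribution only
    through its variance: with sigma_F^2 and Var(eps) both fixed to one,
    the optimal factor effect is a function of beta_gF alone, which keeps
    power comparisons across error families at matched settings.
    """
    m = model_base
    j = np.arange(3.0)
    w = stats.binom.pmf(j, 2, m.p_b)
    eg = float((w * j).sum())
    vg = float((w * (j - eg) ** 2).sum())
    if vg == 0:
        raise ConfigError("degenerate genotype distribution (p_b 0 or 1)")

    bf = np.atleast_1d(np.asarray(beta_F, dtype=float))[:, None]
    s2f = m.sigma2_F
    var_e = m.error.variance()
    mu4_e = 3.0 * var_e**2  # Gaussian-moment convention, see docstring

    c = bf + beta_gF * j  # (m, 3)
    v = c * c * s2f + var_e
    vbar = (w * v).sum(axis=1, keepdims=True)
    slope = ((w * (j - eg)) * v).sum(axis=1) / vg
    # Var(z | g) for z = c^2 F^2 + 2 c F eps + eps^2, F Gaussian:
    var_cond = 2.0 * c**4 * s2f**2 + 4.0 * c * c * s2f * var_e + (mu4_e - var_e**2)
    var_z = (w * var_cond).sum(axis=1) + (w * (v - vbar) ** 2).sum(axis=1)
    out = slope * slope / var_z
    return out if np.ndim(beta_F) else float(out[0])


def optimal_factor_effect(
    beta_gF: float,
    model_base: SimulationModel | None = None,
    grid: np.ndarray | None = None,
) -> float:
    """Factor main effect beta_F maximizing the SVLM power proxy.

    The variance gap between genotype groups — hence the power to detect
    the interaction — is not monotone in the factor's main effect: with no
    main effect the interaction still separates variances, but an
    intermediate beta_F maximizes the separation relative to the noise of
    the squared residuals.  Ties are broken toward smaller \\|beta_F\\|.

    Raises :class:`ConfigError` when beta_gF = 0 (the proxy is then
    constant in what matters and there is nothing to optimize).
    """
    if beta_gF == 0.0:
        raise ConfigError("beta_gF = 0: power proxy is degenerate")
    if model_base is None:
        model_base = SimulationModel()
    if grid is None:
        grid = np.arange(-3.0, 3.0 + 5e-4, 1e-3)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigError("empty beta_F grid")
    vals = svlm_power_proxy(grid, beta_gF, model_base)
    best = vals.max()
    ties = np.flatnonzero(vals == best)
    pick = ties[np.lexsort((grid[ties], np.abs(grid[ties])))[0]]
    return float(grid[pick])


def power_curve(
    beta_gF_grid: Sequence[float],
    *,
    model_base: SimulationModel | None = None,
    n_samples: int = 10_000,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    test: str = "svlm",
    seed: int = 0,
    beta_F: str | float = "optimal",
) -> list[dict]:
    """Power along a beta_gF grid, at the optimal beta_F per point by default.

    Returns one row dict per grid point with the experiment-result columns
    (see ``EXPERIMENT_COLUMNS``).  Row r uses seed ``SeedSequence((seed, r))``
    reduced to a 31-bit integer, so rows are independent and reproducible.
    """
    if model_base is None:
        model_base = SimulationModel()
    rows = []
    for i, bgf in enumerate(beta_gF_grid):
        if beta_F == "optimal":
            bf = optimal_factor_effect(bgf, model_base) if bgf != 0 else 0.0
        else:
            bf = float(beta_F)
        model = replace(model_base, beta_F=bf, beta_gF=float(bgf))
        cfg = ExperimentConfig(
            model=model,
            n_samples=n_samples,
            n_replicates=n_replicates,
            alpha=alpha,
            test=test,
            seed=derive_seed(seed, i),
        )
        est = power(cfg)
        rows.append(experiment_row(cfg, est))
    return rows


def derive_seed(base_seed: int, index: int) -> int:
    """31-bit child seed for row ``index`` of a multi-run experiment."""
    ss = np.random.SeedSequence((int(base_seed), int(index)))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


# ---------------------------------------------------------------------------
# Experiment configs and result tables
# ---------------------------------------------------------------------------

EXPERIMENT_COLUMNS = [
    "test",
    "n",
    "p_B",
    "beta_g",
    "beta_F",
    "beta_gF",
    "error_family",
    "df",
    "n_replicates",
    "rate",
    "se",
    "n_skipped",
    "seed",
]

_CONFIG_KEYS = {
    "test": str,
    "n_samples": int,
    "n_replicates": int,
    "alpha": float,
    "seed": int,
    "genotype_mode": str,
    "p_b": float,
    "mu": float,
    "beta_g": float,
    "beta_f": float,
    "beta_gf": float,
    "mu_f": float,
    "sigma2_f": float,
    "error_family": str,
    "error_df": int,
    "standardize": lambda s: s.strip().lower() in ("1", "true", "yes"),
}


def read_experiment_config(path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a plain key = value file.

    One ``key = value`` pair per line, ``#`` starts a comment, keys are
    case-insensitive.  Recognized keys: test, n_samples, n_replicates,
    alpha, seed, genotype_mode, p_B, mu, beta_g, beta_F, beta_gF, mu_F,
    sigma2_F, error_family, error_df, standardize.  ``n_replicates`` and
    ``seed`` are required; everything else takes the model/experiment
    defaults.
    """
    raw: dict[str, object] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            key = key.lower()
            if key not in _CONFIG_KEYS:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            try:
                raw[key] = _CONFIG_KEYS[key](val)
            except ValueError as exc:
                raise ConfigError(f"{path}:{lineno}: bad value for {key}: {val!r}") from exc
    for req in ("n_replicates", "seed"):
        if req not in raw:
            raise ConfigError(f"{path}: missing required key {req!r}")
    error = ErrorSpec(
        family=raw.get("error_family", "normal"),
        df=raw.get("error_df", 1),
        standardize=raw.get("standardize", True),
    )
    model = SimulationModel(
        p_b=raw.get("p_b", 0.4),
        mu=raw.get("mu", 0.0),
        beta_g=raw.get("beta_g", 0.0),
        beta_F=raw.get("beta_f", 0.0),
        beta_gF=raw.get("beta_gf", 0.0),
        mu_F=raw.get("mu_f", 0.0),
        sigma2_F=raw.get("sigma2_f", 1.0),
        error=error,
    )
    return ExperimentConfig(
        model=model,
        n_replicates=raw["n_replicates"],
        seed=raw["seed"],
        n_samples=raw.get("n_samples", 10_000),
        alpha=raw.get("alpha", 0.05),
        test=raw.get("test", "svlm"),
        genotype_mode=raw.get("genotype_mode", "binomial"),
    )


def experiment_row(config: ExperimentConfig, est: RateEstimate) -> dict:
    """Flatten a (config, estimate) pair into an EXPERIMENT_COLUMNS row."""
    m = config.model
    return {
        "test": config.test,
        "n": config.n_samples,
        "p_B": m.p_b,
        "beta_g": m.beta_g,
        "beta_F": m.beta_F,
        "beta_gF": m.beta_gF,
        "error_family": m.error.family,
        "df": m.error.df if m.error.family == "chisq" else "NA",
        "n_replicates": est.n_replicates,
        "rate": est.rate,
        "se": est.se,
        "n_skipped": est.n_skipped,
        "seed": config.seed,
    }


def write_experiment_results(rows: Iterable[dict], path) -> None:
    """Write experiment rows as TSV with the documented column order."""
    df = pd.DataFrame(list(rows), columns=EXPERIMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Genome-wide scan I/O
# ---------------------------------------------------------------------------


@dataclass
class DosageMatrix:
    """Per-SNP allele dosages for a cohort: SNPs in rows, samples in columns.

    ``a1`` is the effect (dosage-counted) allele, ``a2`` the other allele.
    ``dose`` holds values in [0, 2] with NaN for missing.
    """

    snp_ids: list[str]
    a1: list[str]
    a2: list[str]
    samples: list[str]
    dose: np.ndarray

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != (len(self.snp_ids), len(self.samples)):
            raise ValueError(
                f"dose shape {self.dose.shape} does not match "
                f"{len(self.snp_ids)} SNPs x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP identifiers")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode, encoding="utf-8") if "b" not in mode else open(path, mode)


_DOSAGE_HEADER = ("SNP", "A1", "A2")


def read_dosage_table(path) -> DosageMatrix:
    """Read a text dosage matrix (MACH/minimac-style layout).

    Whitespace-delimited; header line ``SNP A1 A2 <sample ids...>``; one
    SNP per subsequent row with doses in [0, 2] or ``NA``.  Gzip input is
    detected by a ``.gz`` suffix.  Malformed headers, ragged rows,
    duplicate SNP ids and out-of-range doses raise errors naming the
    offending line (and sample column, where applicable).
    """
    with _open_text(path) as fh:
        header = fh.readline().split()
        if len(header) < 4 or tuple(header[:3]) != _DOSAGE_HEADER:
            raise ValueError(
                f"{path}:1: header must start with 'SNP A1 A2' followed by sample ids"
            )
        samples = header[3:]
        if len(set(samples)) != len(samples):
            raise ValueError(f"{path}:1: duplicate sample identifiers in header")
        snp_ids: list[str] = []
        a1: list[str] = []
        a2: list[str] = []
        rows: list[np.ndarray] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, 2):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 3 + len(samples):
                raise ValueError(
                    f"{path}:{lineno}: expected {3 + len(samples)} fields, "
                    f"got {len(tokens)}"
                )
            snp = tokens[0]
            if snp in seen:
                raise ValueError(f"{path}:{lineno}: duplicate SNP id {snp!r}")
            seen.add(snp)
            vals = np.empty(len(samples))
            for j, tok in enumerate(tokens[3:]):
                if tok == "NA":
                    vals[j] = np.nan
                    continue
                try:
                    v = float(tok)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric dose {tok!r} "
                        f"for SNP {snp!r}, sample {samples[j]!r}"
                    ) from None
                if not 0.0 <= v <= 2.0:
                    raise ValueError(
                        f"{path}:{lineno}: dose {v} outside [0, 2] "
                        f"for SNP {snp!r}, sample {samples[j]!r}"
                    )
                vals[j] = v
            snp_ids.append(snp)
            a1.append(tokens[1])
            a2.append(tokens[2])
            rows.append(vals)
    dose = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return DosageMatrix(snp_ids=snp_ids, a1=a1, a2=a2, samples=samples, dose=dose)


def write_dosage_table(dm: DosageMatrix, path) -> None:
    """Write a :class:`DosageMatrix` in the text dialect, doses at 6 decimals."""
    with _open_text(path, "wt") as fh:
        fh.write(" ".join(_DOSAGE_HEADER) + " " + " ".join(dm.samples) + "\n")
        for i in range(dm.n_snps):
            vals = " ".join(
                "NA" if not np.isfinite(v) else f"{v:.6f}" for v in dm.dose[i]
            )
            fh.write(f"{dm.snp_ids[i]} {dm.a1[i]} {dm.a2[i]} {vals}\n")


def read_vcf_dosages(path) -> DosageMatrix:
    """Extract per-sample dosages from a VCF with DS or GP FORMAT fields.

    The effect allele is ALT.  DS is used when present; otherwise the dose
    is computed from genotype probabilities as P(het) + 2*P(hom-alt).
    Multi-allelic records and records carrying neither field are skipped
    with a warning.  Doses are rounded to 6 decimals (FORMAT floats are
    single precision) and clipped to [0, 2].
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    a1: list[str] = []
    a2: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    for variant in vcf:
        vid = variant.ID if variant.ID not in (None, ".") else (
            f"{variant.CHROM}:{variant.POS}"
        )
        if len(variant.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record {vid}", UserWarning)
            continue
        ds = variant.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(len(samples), -1)[:, 0]
        else:
            gp = variant.format("GP")
            if gp is None:
                warnings.warn(
                    f"skipping record {vid}: neither DS nor GP present", UserWarning
                )
                continue
            gp = np.asarray(gp, dtype=float).reshape(len(samples), -1)
            if gp.shape[1] < 3:
                warnings.warn(
                    f"skipping record {vid}: GP has fewer than 3 values", UserWarning
                )
                continue
            dose = gp[:, 1] + 2.0 * gp[:, 2]
        dose = np.asarray(dose, dtype=float)
        dose[dose < 0] = np.nan  # cyvcf2 encodes missing floats as negatives
        dose = np.round(dose, 6)
        np.clip(dose, 0.0, 2.0, out=dose)
        if vid in seen:
            raise ValueError(f"duplicate variant identifier {vid!r} in {path}")
        seen.add(vid)
        snp_ids.append(vid)
        a1.append(variant.ALT[0])
        a2.append(variant.REF)
        rows.append(dose)
    vcf.close()
    dose = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return DosageMatrix(snp_ids=snp_ids, a1=a1, a2=a2, samples=samples, dose=dose)


@dataclass(frozen=True)
class ScanRecord:
    """Combined mean-stage and variance-stage output for one SNP.

    ``mean_*`` fields come from the stage-1 regression of the trait on the
    dosage (so the scan doubles as an ordinary association scan);
    ``var_*`` fields hold the stage-2 SVLM slope or, for the Levene route,
    the Brown–Forsythe p-value alone.  ``status`` is 'ok', 'monomorphic',
    'undefined', or 'low_group_count' (statistics reported, but the
    smallest genotype group is below 80 and SVLM runs conservative there).
    """

    snp_id: str
    effect_allele: str
    n_used: int
    eaf: float
    mean_beta: float
    mean_se: float
    mean_p: float
    var_beta: float
    var_se: float
    var_p: float
    test_used: str
    status: str


def run_scan(
    dm: DosageMatrix,
    pheno: pd.Series,
    covar: pd.DataFrame | None = None,
    test: str = "svlm",
    *,
    max_distance: float = 0.5,
    robust_se: bool = False,
) -> list[ScanRecord]:
    """Apply a variance-heterogeneity test to every SNP of a dosage matrix.

    Samples are matched by identifier between the dosage matrix columns,
    the phenotype series index and the covariate rows; the intersection
    (at least 10 samples) is analyzed with per-SNP listwise deletion.
    ``test='levene'`` converts each dosage row to hard calls first (calls
    farther than ``max_distance`` from an integer become missing).
    Per-SNP failures are recorded in the ``status`` field rather than
    aborting the scan.
    """
    if test not in ("svlm", "levene"):
        raise ValueError(f"unknown test {test!r}")
    order = [s for s in dm.samples if s in set(pheno.index)]
    if covar is not None:
        cset = set(covar.index)
        order = [s for s in order if s in cset]
    if len(order) < 10:
        raise ValueError(
            f"sample intersection too small ({len(order)} < 10)"
        )
    col_idx = {s: i for i, s in enumerate(dm.samples)}
    cols = np.array([col_idx[s] for s in order])
    y = pheno.reindex(order).to_numpy(dtype=float)
    X = covar.reindex(order).to_numpy(dtype=float) if covar is not None else None

    records: list[ScanRecord] = []
    for i in range(dm.n_snps):
        d = dm.dose[i, cols]
        mask = np.isfinite(y) & np.isfinite(d)
        if X is not None and X.shape[1]:
            mask &= np.isfinite(X).all(axis=1)
        n_used = int(mask.sum())
        eaf = float(np.mean(d[mask]) / 2.0) if n_used else float("nan")
        nan = float("nan")
        status = "ok"
        mean_beta = mean_se = mean_p = var_beta = var_se = var_p = nan
        try:
            if test == "svlm":
                res = svlm_test(y, d, X, robust_se=robust_se)
                mean_beta, mean_se, mean_p = res.stage1_beta, res.stage1_se, res.stage1_p
                var_beta, var_se, var_p = res.stage2_beta, res.stage2_se, res.stage2_p
                n_used = res.n_used
                qc_calls = hard_call(d[mask], 0.5)
            else:
                g = hard_call(d, max_distance)
                lres = brown_forsythe_levene(y, g)
                var_p = lres.p_value
                # mean stage on the hard calls, same OLS machinery
                sres = svlm_test(y, g, X, robust_se=robust_se)
                mean_beta, mean_se, mean_p = (
                    sres.stage1_beta,
                    sres.stage1_se,
                    sres.stage1_p,
                )
                n_used = sres.n_used
                qc_calls = g[mask]
            sizes = np.bincount(
                qc_calls[np.isfinite(qc_calls)].astype(np.int64), minlength=3
            )
            present = sizes[sizes > 0]
            if present.size and present.min() < LOW_GROUP_COUNT:
                status = "low_group_count"
        except MonomorphicError:
            status = "monomorphic"
        except (UndefinedStatisticError, RankDeficiencyError):
            status = "undefined"
        records.append(
            ScanRecord(
                snp_id=dm.snp_ids[i],
                effect_allele=dm.a1[i],
                n_used=n_used,
                eaf=eaf,
                mean_beta=mean_beta,
                mean_se=mean_se,
                mean_p=mean_p,
                var_beta=var_beta,
                var_se=var_se,
                var_p=var_p,
                test_used=test,
                status=status,
            )
        )
    return records


_RESULT_COLUMNS = [
    "snp_id",
    "effect_allele",
    "n_used",
    "eaf",
    "mean_beta",
    "mean_se",
    "mean_p",
    "var_beta",
    "var_se",
    "var_p",
    "test_used",
    "status",
]


def _fmt(value, scientific: bool = False) -> str:
    if isinstance(value, float) and not math.isfinite(value):
        return "NA"
    if isinstance(value, float):
        return f"{value:.6e}" if scientific else f"{value:.6g}"
    return str(value)


def write_results(records: Sequence[ScanRecord], path) -> None:
    """Write scan records as TSV, one row per SNP in input order.

    Missing values are written as ``NA``; p-values use scientific notation
    with 6 significant digits after the point.
    """
    if not records:
        raise ValueError("no records to write")
    sci = {"mean_p", "var_p"}
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for rec in records:
            fields = [
                _fmt(getattr(rec, col), scientific=col in sci)
                for col in _RESULT_COLUMNS
            ]
            fh.write("\t".join(fields) + "\n")


def read_results(path) -> pd.DataFrame:
    """Read a scan results TSV back into a DataFrame (NA -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values="NA")
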