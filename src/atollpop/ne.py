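"""Effective population size from one genotype sample.

Two routes:

* the linkage-disequilibrium method — Burrows' composite disequilibrium
  between unphased, unlinked locus pairs, bias-corrected for sample size
  and inverted to Ne (the NeEstimator-style single-sample estimator);
* mutation-drift equilibrium — pi = 4*Ne*mu per generation, solved for Ne
  over a grid of per-year mutation rates times generation time.

Both can legitimately return +infinity: a sample whose LD is fully explained
by sampling noise carries no drift signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .popdata import MISSING, DomainError, GenotypeMatrix, filter_loci

logger = logging.getLogger(__name__)

INF = float("inf")


@dataclass
class MutationModel:
    """Per-site per-year mutation rate range and generation time.

    RAD-sequence mutation rates in fish span roughly 1e-8 to 1e-9 per site
    per year; multiplying by the generation time (years) gives the
    per-generation rate that enters pi = 4*Ne*mu.
    """

    mu_low_per_year: float = 1e-9
    mu_high_per_year: float = 1e-8
    generation_time_years: float = 4.1

    def __post_init__(self) -> None:
        if self.mu_low_per_year <= 0 or self.mu_high_per_year <= 0:
            raise ValueError("mutation rates must be positive")
        if self.generation_time_years <= 0:
            raise ValueError("generation time must be positive")
        if self.mu_low_per_year > self.mu_high_per_year:
            self.mu_low_per_year, self.mu_high_per_year = (
                self.mu_high_per_year,
                self.mu_low_per_year,
            )


@dataclass
class NeEstimate:
    method: str  # "ld" or "pi"
    point: float  # +inf when the corrected r2 signal is <= 0
    ci_low: float
    ci_high: float  # may be +inf
    maf_cutoff: float | None = None
    n_pairs_used: int = 0
    weighted_mean_r2: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if math.isfinite(self.point):
            if not (self.ci_low <= self.point <= self.ci_high):
                raise ValueError("CI must bracket the point estimate")


@dataclass
class R2Table:
    """Per-locus-pair composite r-squared with per-pair sample sizes."""

    pairs: pd.DataFrame  # columns: locus_a, locus_b, r2, n
    n_linked: int  # pairs with r2 > 0.5, the physical-linkage flag
    maf_cutoff: float


def burrows_r2(
    g: GenotypeMatrix,
    maf_cutoff: float = 0.05,
    min_cotyped: int = 2,
    already_filtered: bool = False,
) -> R2Table:
    """Composite linkage disequilibrium r² for every locus pair.

    Burrows' composite Δ̂ is computable from unphased genotype codes: it is
    the sample covariance (n-1 denominator) of the two genotype-code columns
    divided by 2, equivalently (n/(n-1)) * [mean(X*Y)/2 - 2*p*q]. It is
    normalised by the composite allele-frequency variances
    π_A = p(1-p) + D_A (half the genotype-code variance, which absorbs any
    Hardy-Weinberg departure D_A and reduces to p(1-p) at HW proportions):
    r² = Δ̂² / (π_A π_B), i.e. the squared Pearson correlation of the two
    genotype-code columns — identically-typed loci give exactly 1. All
    moments are taken over the individuals co-typed at both loci (pairwise
    deletion). Pairs with fewer than ``min_cotyped`` shared individuals, or
    monomorphic within the shared set, are dropped.
    """
    gf = g if already_filtered else filter_loci(g, maf_min=maf_cutoff, completeness_min=0.0)
    L = gf.n_loci
    if L < 2:
        raise DomainError("need at least two loci past the MAF cutoff")

    present = (gf.calls != MISSING).astype(float)
    X = np.where(gf.calls != MISSING, gf.calls, 0).astype(float)
    X2 = X * X

    S = present.T @ present  # co-typed count per pair
    SX = X.T @ present  # sum of codes at locus a over co-typed individuals
    SY = present.T @ X
    SXY = X.T @ X
    SXX = X2.T @ present
    SYY = present.T @ X2

    iu, ju = np.triu_indices(L, k=1)
    n = S[iu, ju]
    with np.errstate(divide="ignore", invalid="ignore"):
        sx, sy = SX[iu, ju], SY[iu, ju]
        cov = (SXY[iu, ju] - sx * sy / n) / (n - 1.0)
        var_a = (SXX[iu, ju] - sx * sx / n) / (n - 1.0)
        var_b = (SYY[iu, ju] - sy * sy / n) / (n - 1.0)
        delta = cov / 2.0
        denom = (var_a / 2.0) * (var_b / 2.0)  # composite pi_A * pi_B
        r2 = np.where(denom > 0, delta * delta / denom, np.nan)

    ok = (n >= max(min_cotyped, 2)) & (var_a > 0) & (var_b > 0) & ~np.isnan(r2)
    if not ok.any():
        raise DomainError("no usable locus pairs")
    names = [m.id for m in gf.loci]
    pairs = pd.DataFrame(
        {
            "locus_a": [names[i] for i in iu[ok]],
            "locus_b": [names[j] for j in ju[ok]],
            "r2": r2[ok],
            "n": n[ok].astype(int),
        }
    )
    n_linked = int((pairs["r2"] > 0.5).sum())
    if n_linked:
        logger.info("%d locus pairs with r2 > 0.5 (possible physical linkage)", n_linked)
    return R2Table(pairs=pairs, n_linked=n_linked, maf_cutoff=maf_cutoff)


def expected_sampling_r2(S: float, mating: str = "random") -> float:
    """Expected contribution of finite sampling to r̄² at sample size S.

    Two empirically calibrated regimes: S >= 30 uses 1/S + 3.19/S²; smaller
    samples use 0.0018 + 0.907/S + 4.44/S². (Mating system does not enter
    the sampling expectation.)
    """
    if S <= 1:
        raise DomainError("sample size must exceed 1")
    if S >= 30:
        return 1.0 / S + 3.19 / (S * S)
    return 0.0018 + 0.907 / S + 4.44 / (S * S)


def _invert_r2prime(r2p: float, S: float, mating: str) -> float:
    """Solve the calibrated drift relation for Ne given corrected r²'."""
    if r2p <= 0:
        return INF
    if mating == "random":
        a, b = (1.0 / 3.0, 2.76) if S >= 30 else (0.308, 2.08)
    elif mating == "monogamy":
        a, b = (2.0 / 3.0, 7.2) if S >= 30 else (0.618, 5.24)
    else:
        raise ValueError(f"unknown mating model {mating!r}")
    disc = a * a - b * r2p
    if disc < 0:
        logger.warning("negative discriminant at r2'=%.4g; reporting infinity", r2p)
        return INF
    ne = (a + math.sqrt(disc)) / (2.0 * r2p)
    return ne if ne > 0 else INF


def ld_ne_estimate(
    r2_table: R2Table,
    mating: str = "random",
    alpha: float = 0.05,
    exclude_linked: bool = False,
) -> NeEstimate:
    """Single-sample LD estimate of Ne with sample-size bias correction.

    r̄² is the mean over locus pairs weighted by the per-pair co-typed
    sample size (the missing-data incorporation); the sampling expectation
    at the harmonic-mean sample size S is subtracted, and the corrected r²'
    inverted to Ne. r²' <= 0 means the observed LD is within sampling noise
    and the point estimate is +infinity.

    The parametric confidence interval treats n_pairs * r̄²/E[r̄²] as
    chi-square with the number of pairs as degrees of freedom (pairs sharing
    loci are correlated, so this is an approximation that narrows the true
    interval); each r̄² bound is corrected and inverted like the point
    estimate, and the upper Ne bound is frequently +infinity.

    ``exclude_linked`` drops pairs with r² > 0.5 (putative physical linkage)
    before averaging; retained by default.
    """
    df = r2_table.pairs
    if exclude_linked:
        df = df[df["r2"] <= 0.5]
    if df.empty:
        raise DomainError("no locus pairs to average")
    w = df["n"].to_numpy(dtype=float)
    r2 = df["r2"].to_numpy(dtype=float)
    r2_bar = float(np.sum(w * r2) / np.sum(w))
    S_harm = float(len(df) / np.sum(1.0 / df["n"].to_numpy(dtype=float)))
    e_samp = expected_sampling_r2(S_harm, mating)

    point = _invert_r2prime(r2_bar - e_samp, S_harm, mating)

    n_pairs = len(df)
    chi_hi = stats.chi2.ppf(1.0 - alpha / 2.0, df=n_pairs)
    chi_lo = stats.chi2.ppf(alpha / 2.0, df=n_pairs)
    r2_lo = n_pairs * r2_bar / chi_hi  # smaller r2 -> larger Ne
    r2_hi = n_pairs * r2_bar / chi_lo
    ci_high = _invert_r2prime(r2_lo - e_samp, S_harm, mating)
    ci_low = _invert_r2prime(r2_hi - e_samp, S_harm, mating)
    if ci_low > point:  # both bounds can collapse to inf alongside the point
        ci_low = min(ci_low, point)
    return NeEstimate(
        method="ld",
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        maf_cutoff=r2_table.maf_cutoff,
        n_pairs_used=n_pairs,
        weighted_mean_r2=r2_bar,
        params={
            "harmonic_mean_S": S_harm,
            "expected_sampling_r2": e_samp,
            "mating": mating,
            "alpha": alpha,
            "n_linked_pairs": r2_table.n_linked,
            "exclude_linked": exclude_linked,
        },
    )


def pi_ne_estimate(
    pi: float, model: MutationModel, n_grid: int = 2
) -> NeEstimate:
    """Ne from nucleotide diversity at mutation-drift equilibrium.

    Ne = pi / (4 * mu_per_generation) with mu_per_generation = per-year rate
    times generation time. Evaluated over a log-spaced grid spanning the
    model's mutation-rate range; the bounds are the extreme values (the high
    bound comes from the lowest rate) and the point is taken at the
    geometric-mean rate.
    """
    if pi < 0:
        raise DomainError("pi must be non-negative")
    T = model.generation_time_years
    mus = np.geomspace(model.mu_low_per_year, model.mu_high_per_year, max(n_grid, 2))
    if T * mus[0] == 0:
        raise DomainError("mu * T must be positive")
    ne_grid = pi / (4.0 * mus * T)
    mu_mid = math.sqrt(model.mu_low_per_year * model.mu_high_per_year)
    return NeEstimate(
        method="pi",
        point=float(pi / (4.0 * mu_mid * T)),
        ci_low=float(ne_grid.min()),
        ci_high=float(ne_grid.max()),
        params={
            "pi": pi,
            "mu_low_per_year": model.mu_low_per_year,
            "mu_high_per_year": model.mu_high_per_year,
            "generation_time_years": T,
            "ne_grid": ne_grid.tolist(),
        },
    )


def ne_over_n(ne: NeEstimate, n: float) -> dict[str, float]:
    """Elementwise Ne/N for the point estimate and both bounds.

    +infinity in Ne propagates to the ratio (flagged by being non-finite).
    """
    if n <= 0:
        raise DomainError("census size must be positive")
    return {
        "point": ne.point / n,
        "low": ne.ci_low / n,
        "high": ne.ci_high / n,
    }
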