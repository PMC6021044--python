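"""Census population size from visual transect surveys.

Transect counts become densities (individuals per hectare), densities scale
by planar habitat area into per-year population sizes, and the harmonic mean
across sampling years gives the census estimate N. The harmonic mean is used
because genetic drift over fluctuating years is governed by the smallest
yearly sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .popdata import AbsentDataError, DomainError, HabitatModel, SurveyTable

M2_PER_HA = 10_000.0


@dataclass
class DensityEstimate:
    species: str
    year: int
    stratum: str  # shallow, deep, or pooled
    density_ind_per_ha: float
    n_transects: int


@dataclass
class CensusEstimate:
    """Harmonic-mean census size with its per-year components."""

    species: str
    N_by_year: dict[int, float]
    N: float
    harmonic_mean_density: float
    depth_range: str
    effective_area_ha: float


def annual_density(
    table: SurveyTable,
    species: str,
    year: int,
    strata: Sequence[str] = ("shallow", "deep"),
) -> DensityEstimate:
    """Density = total count / total transect area over matching transects,
    converted to individuals per hectare."""
    df = table.df
    m = (df["species"] == species) & (df["year"] == year) & df["stratum"].isin(strata)
    sub = df[m]
    if sub.empty:
        raise AbsentDataError(
            f"no transects for {species!r} in {year} (strata {list(strata)})"
        )
    density = sub["count"].sum() / sub["transect_area_m2"].sum() * M2_PER_HA
    label = strata[0] if len(strata) == 1 else "pooled"
    return DensityEstimate(
        species=species,
        year=year,
        stratum=label,
        density_ind_per_ha=float(density),
        n_transects=len(sub),
    )


def densities_by_year(
    table: SurveyTable, species: str, strata: Sequence[str] = ("shallow", "deep")
) -> dict[int, float]:
    """Pooled annual densities (ind/ha) for one species across all years in
    which it was surveyed."""
    out: dict[int, float] = {}
    for year in table.years:
        try:
            out[year] = annual_density(table, species, year, strata).density_ind_per_ha
        except AbsentDataError:
            continue
    if not out:
        raise AbsentDataError(f"no transects at all for {species!r}")
    return out


def harmonic_mean(values: Sequence[float]) -> float:
    """k / sum(1/v). Undefined for non-positive values."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise DomainError("harmonic mean of an empty sequence")
    if np.any(v <= 0):
        raise DomainError("harmonic mean requires strictly positive values")
    return float(v.size / np.sum(1.0 / v))


def census_size(
    densities: Mapping[int, float],
    habitat: HabitatModel,
    depth_range: str = "to_100m",
    species: str = "",
) -> CensusEstimate:
    """Harmonic-mean census size over years.

    Per-year N = density x effective habitat area (shallow area plus the
    deep area discounted by the species' deep-density factor); the returned
    N is the harmonic mean of the per-year values. With constant habitat
    this equals the harmonic-mean density times the area.
    """
    if not densities:
        raise DomainError("need at least one year of density")
    area_ha = habitat.effective_area_ha(depth_range)
    if area_ha <= 0:
        raise DomainError("habitat area is zero")
    n_by_year = {int(y): float(d) * area_ha for y, d in densities.items()}
    hm_density = harmonic_mean(list(densities.values()))
    return CensusEstimate(
        species=species,
        N_by_year=n_by_year,
        N=harmonic_mean(list(n_by_year.values())),
        harmonic_mean_density=hm_density,
        depth_range=depth_range,
        effective_area_ha=area_ha,
    )


def species_ratio(a: float | CensusEstimate, b: float | CensusEstimate) -> float:
    """Ratio of two abundances (densities or census N); b is the denominator."""
    va = a.N if isinstance(a, CensusEstimate) else float(a)
    vb = b.N if isinstance(b, CensusEstimate) else float(b)
    if vb == 0:
        raise DomainError("zero denominator in species ratio")
    return va / vb


# ---------------------------------------------------------------------------
# Density trend model comparison
# ---------------------------------------------------------------------------


@dataclass
class TrendFit:
    model: str  # linear or exponential
    params: tuple[float, ...]
    rss: float
    aicc: float
    fitted: np.ndarray = field(repr=False, default=None)


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        raise DomainError(f"AICc undefined for n={n}, k={k}")
    rss = max(rss, 1e-300)  # a perfect fit has AICc -> -inf; keep it finite
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def trend_aicc(densities: Mapping[int, float], model: str) -> TrendFit:
    """Least-squares fit of a linear or exponential year trend with AICc.

    The exponential model y = a*exp(b*t) is fitted by nonlinear least
    squares on the original scale (a log-linear fit would misweight large
    years); k counts the two curve parameters plus one for the error
    variance. AICc values are comparable between models on the same data.
    """
    years = np.array(sorted(densities), dtype=float)
    y = np.array([densities[int(t)] for t in years], dtype=float)
    n = len(y)
    k = 3  # intercept/scale, slope/rate, error variance
    if n - k - 1 <= 0:
        raise DomainError(f"need at least {k + 2} years for AICc (got {n})")
    t = years - years[0]  # offset for conditioning; fit is translation-equivariant

    if model == "linear":
        slope, intercept, *_ = stats.linregress(t, y)
        fitted = intercept + slope * t
        rss = float(np.sum((y - fitted) ** 2))
        return TrendFit("linear", (intercept, slope), rss, _aicc(rss, n, k), fitted)

    if model == "exponential":
        # log-linear start point, then NLS on the original scale
        pos = np.clip(y, 1e-9, None)
        b0, loga0, *_ = stats.linregress(t, np.log(pos))
        a0 = float(np.exp(loga0))

        def f(tt, a, b):
            return a * np.exp(b * tt)

        try:
            popt, _ = optimize.curve_fit(f, t, y, p0=(a0, b0), maxfev=10_000)
        except RuntimeError:
            popt = (a0, b0)
        fitted = f(t, *popt)
        rss = float(np.sum((y - fitted) ** 2))
        return TrendFit(
            "exponential", tuple(float(p) for p in popt), rss, _aicc(rss, n, k), fitted
        )

    raise ValueError(f"unknown trend model {model!r}")


def compare_trends(densities: Mapping[int, float]) -> dict[str, TrendFit]:
    """Fit both trend models; the one with the lower AICc is preferred."""
    return {m: trend_aicc(densities, m) for m in ("linear", "exponential")}
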