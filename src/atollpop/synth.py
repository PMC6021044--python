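"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* a forward Wright-Fisher simulator (ideal diploid population, random
  mating, unlinked biallelic loci, optional symmetric mutation) whose true
  N equals Ne by construction — the truth set for drift and LD-based Ne;
* a pedigree generator (founders + Mendelian transmission) emitting true
  relationship labels — the truth set for kinship binning;
* a transect-survey generator with Poisson counts around stratum densities
  and an optional year trend — the truth set for the census chain.

All generators are bit-reproducible from their config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .popdata import GenotypeMatrix, LocusMeta, SurveyTable

TRANSECT_AREA_M2 = 250.0  # 50 m x 5 m swath


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulation
# ---------------------------------------------------------------------------


@dataclass
class WFConfig:
    """Ideal-population simulation: N_true diploids, discrete generations,
    random mating with replacement, free recombination between loci.

    Defaults mirror the desk-scale parameter-recovery condition: true
    Ne = 100 with 50 sampled individuals and 200 unlinked loci. 60
    generations of burn-in let genotypic LD reach drift-recombination
    equilibrium (unlinked LD halves each generation, so a few tens of
    generations suffice) without losing most loci to fixation. Initial
    frequencies "uniform" draws each locus's frequency from U(0.05, 0.95).
    """

    N_true: int = 100
    generations: int = 60
    L: int = 200
    mu: float = 0.0
    init_freq: float | str = "uniform"
    sample_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.N_true, self.generations, self.L) <= 0:
            raise ValueError("N_true, generations, L must be positive")
        if not (0 < self.sample_size <= self.N_true):
            raise ValueError("sample_size must be in (0, N_true]")
        if self.mu < 0 or self.mu >= 0.5:
            raise ValueError("mu must be in [0, 0.5)")
        if isinstance(self.init_freq, str):
            if self.init_freq != "uniform":
                raise ValueError("init_freq must be a frequency or 'uniform'")
        elif not (0.0 <= float(self.init_freq) <= 1.0):
            raise ValueError("init_freq must lie in [0, 1]")


def simulate_wf_population(cfg: WFConfig) -> tuple[GenotypeMatrix, dict]:
    """Run the Wright-Fisher simulation and sample genotypes at the end.

    Returns the sampled genotype matrix plus a truth record with the
    configuration, the per-generation allele-frequency trajectories, and
    the per-generation population expected heterozygosity (whose mean decay
    follows (1 - 1/(2N))^t without mutation).
    """
    rng = np.random.default_rng(cfg.seed)
    N, L = cfg.N_true, cfg.L
    if cfg.init_freq == "uniform":
        p0 = rng.uniform(0.05, 0.95, size=L)
    else:
        p0 = np.full(L, float(cfg.init_freq))
    # haplotypes: (individual, chromosome copy, locus)
    pop = (rng.random((N, 2, L)) < p0[None, None, :]).astype(np.int8)

    traj = np.empty((cfg.generations + 1, L), dtype=float)
    traj[0] = pop.mean(axis=(0, 1))
    locus_idx = np.arange(L)[None, :]
    for t in range(1, cfg.generations + 1):
        mothers = rng.integers(N, size=N)
        fathers = rng.integers(N, size=N)
        pick_m = rng.integers(2, size=(N, L))
        pick_f = rng.integers(2, size=(N, L))
        child = np.empty((N, 2, L), dtype=np.int8)
        child[:, 0, :] = pop[mothers[:, None], pick_m, locus_idx]
        child[:, 1, :] = pop[fathers[:, None], pick_f, locus_idx]
        if cfg.mu > 0:
            flips = rng.random((N, 2, L)) < cfg.mu
            child ^= flips.astype(np.int8)
        pop = child
        traj[t] = pop.mean(axis=(0, 1))

    chosen = rng.choice(N, size=cfg.sample_size, replace=False)
    calls = pop[chosen].sum(axis=1).astype(np.int8)
    g = GenotypeMatrix(
        individuals=[f"wf_{i:04d}" for i in range(cfg.sample_size)],
        loci=[LocusMeta(id=f"L{j:05d}", chrom="sim", pos=j + 1, ref="A", alt="C")
              for j in range(L)],
        calls=calls,
    )
    het = 2.0 * traj * (1.0 - traj)
    truth = {
        "config": asdict(cfg),
        "N_true": N,
        "trajectories": traj,
        "mean_het_by_generation": het.mean(axis=1),
        "final_freqs": traj[-1],
    }
    return g, truth


# ---------------------------------------------------------------------------
# Pedigreed families
# ---------------------------------------------------------------------------


@dataclass
class PedigreeConfig:
    """Families of full- and half-sib offspring over unrelated founders.

    Each family has a mother and father producing ``n_fullsib_offspring``;
    ``n_halfsib_offspring`` further offspring come from the same father and
    a second mother (half sibs of the first set). Founder allele frequencies
    are drawn per locus from U(freq_low, freq_high). Defaults give
    100 families x (2 full sibs + 1 half sib) = 100 true full-sib pairs and
    200 half-sib pairs at 1000 loci, enough for the per-pair kinship
    standard error to sit well below the 0.25 vs 0.125 bin separation.
    """

    n_families: int = 100
    n_fullsib_offspring: int = 2
    n_halfsib_offspring: int = 1
    L: int = 1000
    freq_low: float = 0.1
    freq_high: float = 0.9
    include_founders: bool = False
    duplicate_first: bool = False  # re-emit the first offspring as a copy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families <= 0 or self.L <= 0:
            raise ValueError("n_families and L must be positive")
        if self.n_fullsib_offspring < 0 or self.n_halfsib_offspring < 0:
            raise ValueError("offspring counts must be non-negative")
        if not (0.0 < self.freq_low <= self.freq_high < 1.0):
            raise ValueError("founder frequency range must sit inside (0, 1)")


def _mate(rng: np.random.Generator, mother: np.ndarray, father: np.ndarray) -> np.ndarray:
    L = mother.shape[1]
    idx = np.arange(L)
    return np.stack(
        [mother[rng.integers(2, size=L), idx], father[rng.integers(2, size=L), idx]]
    )


def simulate_pedigree_genotypes(cfg: PedigreeConfig) -> tuple[GenotypeMatrix, dict]:
    """Generate pedigreed genotypes plus the true label for every pair.

    Labels: full_sib (same parent pair), half_sib (exactly one shared
    parent), parent_offspring, duplicate (re-emitted copy), unrelated.
    """
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.freq_low, cfg.freq_high, size=cfg.L)

    def founder() -> np.ndarray:
        return (rng.random((2, cfg.L)) < p[None, :]).astype(np.int8)

    haplos: list[np.ndarray] = []
    names: list[str] = []
    parents: dict[str, tuple[str, str] | None] = {}

    for f in range(cfg.n_families):
        mother, father = founder(), founder()
        mother2 = founder() if cfg.n_halfsib_offspring else None
        m_id, d_id, m2_id = f"mom{f:03d}", f"dad{f:03d}", f"mom{f:03d}b"
        if cfg.include_founders:
            for nm, hap in ((m_id, mother), (d_id, father)):
                names.append(nm)
                haplos.append(hap)
                parents[nm] = None
            if mother2 is not None:
                names.append(m2_id)
                haplos.append(mother2)
                parents[m2_id] = None
        for o in range(cfg.n_fullsib_offspring):
            nm = f"fam{f:03d}_fs{o}"
            names.append(nm)
            haplos.append(_mate(rng, mother, father))
            parents[nm] = (m_id, d_id)
        for o in range(cfg.n_halfsib_offspring):
            nm = f"fam{f:03d}_hs{o}"
            names.append(nm)
            haplos.append(_mate(rng, mother2, father))
            parents[nm] = (m2_id, d_id)

    duplicates: set[tuple[str, str]] = set()
    if cfg.duplicate_first:
        names.append(names[0] + "_dup")
        haplos.append(haplos[0].copy())
        parents[names[-1]] = parents[names[0]]
        duplicates.add((names[0], names[-1]))

    calls = np.stack([h.sum(axis=0) for h in haplos]).astype(np.int8)
    g = GenotypeMatrix(
        individuals=names,
        loci=[LocusMeta(id=f"P{j:05d}", chrom="ped", pos=j + 1, ref="A", alt="C")
              for j in range(cfg.L)],
        calls=calls,
    )

    labels: dict[tuple[str, str], str] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pa, pb = parents[a], parents[b]
            if (a, b) in duplicates or (b, a) in duplicates:
                lab = "duplicate"
            elif pa is not None and pb is not None:
                shared = len(set(pa) & set(pb))
                lab = {2: "full_sib", 1: "half_sib", 0: "unrelated"}[shared]
            elif pa is not None and b in pa or pb is not None and a in pb:
                lab = "parent_offspring"
            else:
                lab = "unrelated"
            labels[(a, b)] = lab
    truth = {"config": asdict(cfg), "labels": labels, "founder_freqs": p}
    return g, truth


# ---------------------------------------------------------------------------
# Transect surveys
# ---------------------------------------------------------------------------


@dataclass
class SurveySimConfig:
    """Visual-census emulation: four expedition years, two depth strata,
    73 transects of 250 m² in total (47 shallow, 26 deep), Poisson counts.

    ``base_density`` is the year-one density (ind/ha) per stratum; the
    defaults echo an angelfish-like species with ~160 ind/ha shallow and
    half that at depth. ``trend`` multiplies density over years: "none",
    "linear" (1 + rate * t), or "exponential" (exp(rate * t)) with t in
    years since the first survey.
    """

    years: tuple[int, ...] = (1998, 2005, 2010, 2016)
    n_shallow_transects: int = 47
    n_deep_transects: int = 26
    base_density: dict = field(
        default_factory=lambda: {"shallow": 160.0, "deep": 80.0}
    )
    trend: str = "none"
    trend_rate: float = 0.0
    transect_area_m2: float = TRANSECT_AREA_M2
    species: str = "sim_species"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trend not in ("none", "linear", "exponential"):
            raise ValueError(f"unknown trend {self.trend!r}")
        if any(d < 0 for d in self.base_density.values()):
            raise ValueError("densities must be non-negative")
        if self.transect_area_m2 <= 0:
            raise ValueError("transect area must be positive")


def _split_across_years(total: int, n_years: int) -> list[int]:
    base, extra = divmod(total, n_years)
    return [base + (1 if i < extra else 0) for i in range(n_years)]


def simulate_survey(cfg: SurveySimConfig) -> tuple[SurveyTable, dict]:
    """Draw per-transect Poisson counts and return the table plus truth.

    Expected count per transect = density(year, stratum) x area / 10,000.
    The truth record carries the generating density for every year/stratum.
    """
    rng = np.random.default_rng(cfg.seed)
    years = list(cfg.years)
    t0 = years[0]
    per_year = {
        "shallow": _split_across_years(cfg.n_shallow_transects, len(years)),
        "deep": _split_across_years(cfg.n_deep_transects, len(years)),
    }

    def density(stratum: str, year: int) -> float:
        d0 = cfg.base_density.get(stratum, 0.0)
        t = year - t0
        if cfg.trend == "linear":
            return max(d0 * (1.0 + cfg.trend_rate * t), 0.0)
        if cfg.trend == "exponential":
            return d0 * float(np.exp(cfg.trend_rate * t))
        return d0

    rows = []
    true_density: dict[str, dict[int, float]] = {"shallow": {}, "deep": {}}
    tn = 0
    for yi, year in enumerate(years):
        for stratum in ("shallow", "deep"):
            d = density(stratum, year)
            true_density[stratum][year] = d
            lam = d * cfg.transect_area_m2 / 10_000.0
            for _ in range(per_year[stratum][yi]):
                tn += 1
                rows.append(
                    {
                        "site": f"T{tn:03d}",
                        "year": year,
                        "stratum": stratum,
                        "transect_area_m2": cfg.transect_area_m2,
                        "species": cfg.species,
                        "count": int(rng.poisson(lam)),
                    }
                )
    table = SurveyTable(df=pd.DataFrame(rows))
    truth = {"config": asdict(cfg), "density": true_density}
    return table, truth


def save_truth(truth: dict, path: str | Path) -> None:
    """Write a truth record as JSON (numpy arrays become lists, tuple keys
    become 'a|b' strings) — the sidecar convention that keeps the genotype
    and survey files themselves fully standard."""

    def conv(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {
                ("|".join(map(str, k)) if isinstance(k, tuple) else str(k)): conv(v)
                for k, v in obj.items()
            }
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        return obj

    Path(path).write_text(json.dumps(conv(truth), indent=2, sort_keys=True))
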