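"""Published study inputs for the two Clipperton Atoll endemics.

These are the worked-example inputs of the package: yearly visual-census
densities (individuals per hectare, pooled over strata), planar habitat
areas from the bathymetric survey, per-species deep-density discounts,
per-SNP-data diversity values, and the life-history constants entering the
pi-based Ne conversion. They are data, not parameters to fit.
"""

from __future__ import annotations

from .ne import MutationModel
from .popdata import HabitatModel

#: Planar reef habitat to 50 m depth (km^2).
SHALLOW_AREA_KM2 = 2.838
#: Additional reef habitat between 50 and 100 m (km^2).
DEEP_AREA_KM2 = 2.287

#: Per-site per-year RAD mutation-rate range for fish.
MU_LOW_PER_YEAR = 1e-9
MU_HIGH_PER_YEAR = 1e-8

ANGELFISH = "H. limbaughi"
DAMSELFISH = "S. baldwini"

#: Yearly pooled densities (ind/ha) from the four expeditions.
DENSITIES = {
    ANGELFISH: {1998: 61.0, 2005: 168.0, 2010: 190.0, 2016: 237.0},
    DAMSELFISH: {1998: 806.0, 2005: 1856.0, 2010: 2425.0, 2016: 7171.0},
}

#: Deep (50-100 m) density as a fraction of shallow density. The angelfish
#: occurs at undiminished density to ~100 m; the damselfish thins out
#: five-fold below 50 m.
DEEP_DENSITY_FACTOR = {ANGELFISH: 1.0, DAMSELFISH: 0.2}

#: Generation times (years) from the closest congeners with data.
GENERATION_TIME_YEARS = {ANGELFISH: 4.1, DAMSELFISH: 2.6}

#: Published per-site nucleotide diversity of the RAD data.
PI = {ANGELFISH: 0.0009, DAMSELFISH: 0.0008}

#: Published single-sample LD point estimates of Ne (upper CI unbounded).
LD_NE_POINT = {ANGELFISH: 109.0, DAMSELFISH: 375.9}

#: Sample sizes of the genetic collections.
N_GENETIC_SAMPLES = {ANGELFISH: 35, DAMSELFISH: 24}


def habitat_for(species: str) -> HabitatModel:
    """Habitat model with the species' deep-density discount."""
    return HabitatModel(
        shallow_area_km2=SHALLOW_AREA_KM2,
        deep_area_km2=DEEP_AREA_KM2,
        deep_density_factor=DEEP_DENSITY_FACTOR[species],
    )


def mutation_model_for(species: str) -> MutationModel:
    return MutationModel(
        mu_low_per_year=MU_LOW_PER_YEAR,
        mu_high_per_year=MU_HIGH_PER_YEAR,
        generation_time_years=GENERATION_TIME_YEARS[species],
    )
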