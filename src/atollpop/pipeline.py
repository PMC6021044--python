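"""End-to-end orchestration: census -> diversity -> kinship -> Ne -> Ne/N.

``run_pipeline`` is the single entry point behind the numbered analysis
drivers. It accepts either a survey CSV or direct yearly densities for the
census side, and optionally a genotype file for the genetic side; every
stage's output lands in one results dictionary (JSON-serialisable, with
infinities encoded as the string "inf") so a re-run with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import census as cen
from . import diversity as div
from . import kinship as kin
from . import ne as nemod
from .popdata import GenotypeMatrix, HabitatModel, filter_loci, read_genotypes, read_survey_csv

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, with the study's defaults.

    Exactly one of ``survey_csv`` / ``densities_by_year`` feeds the census
    stage; ``genotype_path`` (+ ``genotype_format``) optionally feeds the
    genetic stages.
    """

    species: str
    habitat: HabitatModel
    mutation: nemod.MutationModel
    survey_csv: str | Path | None = None
    densities_by_year: dict[int, float] | None = None
    genotype_path: str | Path | None = None
    genotype_format: str = "vcf"
    assayed_loci: int | None = None
    maf_min: float = 0.05
    completeness_min: float = 0.8
    kin_scheme: kin.KinBinScheme = field(default_factory=kin.KinBinScheme)
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.survey_csv is None) == (self.densities_by_year is None):
            raise ValueError("provide exactly one of survey_csv or densities_by_year")
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if not (0.0 <= self.completeness_min <= 1.0):
            raise ValueError("completeness_min must be in [0, 1]")
        for p in (self.survey_csv, self.genotype_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


def _encode(obj):
    """JSON encoding with explicit 'inf' tokens and numpy scalars unwrapped."""
    if isinstance(obj, dict):
        return {str(k): _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _encode(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isinf(f):
            return "inf" if f > 0 else "-inf"
        if math.isnan(f):
            return "nan"
        return f
    if isinstance(obj, np.integer):
        return int(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _encode(dataclasses.asdict(obj))
    return obj


def _census_stage(cfg: PipelineConfig) -> dict:
    if cfg.densities_by_year is not None:
        densities = {int(y): float(d) for y, d in cfg.densities_by_year.items()}
    else:
        table = read_survey_csv(cfg.survey_csv)
        densities = cen.densities_by_year(table, cfg.species)
    shallow = cen.census_size(densities, cfg.habitat, "shallow_only", cfg.species)
    full = cen.census_size(densities, cfg.habitat, "to_100m", cfg.species)
    out = {
        "densities_by_year": densities,
        "mean_density": float(np.mean(list(densities.values()))),
        "harmonic_mean_density": shallow.harmonic_mean_density,
        "N_shallow": shallow.N,
        "N_full": full.N,
        "N_by_year_shallow": shallow.N_by_year,
        "N_by_year_full": full.N_by_year,
        "effective_area_ha": {
            "shallow_only": shallow.effective_area_ha,
            "to_100m": full.effective_area_ha,
        },
    }
    if len(densities) >= 5:  # AICc needs n >= k+2
        fits = cen.compare_trends(densities)
        out["trend"] = {
            m: {"aicc": f.aicc, "rss": f.rss, "params": list(f.params)}
            for m, f in fits.items()
        }
    return out


def _genetic_stage(cfg: PipelineConfig, g: GenotypeMatrix) -> dict:
    gf = filter_loci(g, maf_min=cfg.maf_min, completeness_min=cfg.completeness_min)
    report = div.diversity_report(gf, assayed_loci=cfg.assayed_loci)
    out: dict = {"diversity": dataclasses.asdict(report),
                 "n_loci_prefilter": g.n_loci, "n_loci_postfilter": gf.n_loci}

    kr = kin.classify_kinship(kin.loiselle_matrix(gf), cfg.kin_scheme)
    net = kin.kin_network(kr, level="half_sib")
    out["kinship"] = {
        "n_comparisons": kr.n_comparisons,
        "counts": kr.counts,
        "percentages": kr.percentages,
        "n_connected_half_sib": net["n_connected"],
        "n_components_half_sib": len(net["components"]),
        "n_flagged_identical": len(kr.flagged_pairs),
    }

    try:
        r2 = nemod.burrows_r2(gf, maf_cutoff=cfg.maf_min, already_filtered=True)
        ld = nemod.ld_ne_estimate(r2)
        out["ne_ld"] = dataclasses.asdict(ld)
    except nemod.DomainError as exc:
        logger.warning("LD Ne unavailable: %s", exc)
        out["ne_ld"] = None

    pi_est = nemod.pi_ne_estimate(report.pi_per_site, cfg.mutation)
    out["ne_pi"] = dataclasses.asdict(pi_est)

    sib = kin.drop_fullsibs_and_recompute(gf, kr, assayed_loci=cfg.assayed_loci)
    out["sib_removal"] = {
        "removed": sib["removed"],
        "n_sib_pairs": sib["n_sib_pairs"],
        "delta": sib["delta"],
    }
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every configured stage and return (and optionally write) the
    results bundle. Stage failures propagate with the stage name; stages
    already completed are preserved in the written bundle."""
    results: dict = {
        "species": cfg.species,
        "seed": cfg.seed,
        "config": {
            "habitat": dataclasses.asdict(cfg.habitat),
            "mutation": dataclasses.asdict(cfg.mutation),
            "maf_min": cfg.maf_min,
            "completeness_min": cfg.completeness_min,
            "kin_scheme": dataclasses.asdict(cfg.kin_scheme),
        },
    }
    stage = "census"
    try:
        results["census"] = _census_stage(cfg)
        if cfg.genotype_path is not None:
            stage = "genetics"
            g = read_genotypes(cfg.genotype_path, cfg.genotype_format)
            results.update(_genetic_stage(cfg, g))
            stage = "ne_over_n"
            ratios: dict = {}
            for label, N in (
                ("shallow", results["census"]["N_shallow"]),
                ("full", results["census"]["N_full"]),
            ):
                pi_ne = results["ne_pi"]
                ratios[f"pi_ne/{label}"] = {
                    "low": pi_ne["ci_low"] / N,
                    "high": pi_ne["ci_high"] / N,
                }
                if results.get("ne_ld"):
                    ratios[f"ld_ne/{label}"] = {
                        "point": results["ne_ld"]["point"] / N,
                        "high": results["ne_ld"]["ci_high"] / N,
                    }
            results["ne_over_n"] = ratios
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        if cfg.out_dir is not None:
            write_results(results, cfg.out_dir, cfg.species)
    return results


def write_results(results: dict, out_dir: str | Path, species: str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slug = species.replace(" ", "_").replace(".", "").lower()
    path = out_dir / f"results_{slug}.json"
    path.write_text(json.dumps(_encode(results), indent=2, sort_keys=True))
    return path
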