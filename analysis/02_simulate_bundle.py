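#!/usr/bin/env python
"""Generate the synthetic data bundle used by the downstream drivers.

Produces, under scratch/sim/ (bulky, regenerated on demand):
  * a Wright-Fisher genotype sample (true Ne = 100, 50 individuals,
    200 unlinked loci) in Genepop and VCF with its truth JSON;
  * a pedigreed sample (100 families, full- and half-sib offspring) in
    Genepop with true pair labels;
  * a four-year, two-stratum transect survey CSV with true densities.

Everything is reproducible from the seeds printed below.
"""

from pathlib import Path

from atollpop import (
    PedigreeConfig,
    SurveySimConfig,
    WFConfig,
    simulate_pedigree_genotypes,
    simulate_survey,
    simulate_wf_population,
    write_genotypes,
)
from atollpop.popdata import write_survey_csv
from atollpop.synth import save_truth

SIM = Path(__file__).resolve().parents[1] / "scratch" / "sim"
SEED = 2026


def main() -> None:
    SIM.mkdir(parents=True, exist_ok=True)

    wf_cfg = WFConfig(seed=SEED)
    g_wf, wf_truth = simulate_wf_population(wf_cfg)
    write_genotypes(g_wf, SIM / "wf_sample.gen", "genepop")
    write_genotypes(g_wf, SIM / "wf_sample.vcf", "vcf")
    save_truth(wf_truth, SIM / "wf_truth.json")
    print(f"Wright-Fisher: N_true={wf_cfg.N_true}, {g_wf.n_individuals} sampled, "
          f"{g_wf.n_loci} loci, seed {SEED}")

    ped_cfg = PedigreeConfig(seed=SEED)
    g_ped, ped_truth = simulate_pedigree_genotypes(ped_cfg)
    write_genotypes(g_ped, SIM / "pedigree.gen", "genepop")
    save_truth(ped_truth, SIM / "pedigree_truth.json")
    n_fs = sum(1 for l in ped_truth["labels"].values() if l == "full_sib")
    n_hs = sum(1 for l in ped_truth["labels"].values() if l == "half_sib")
    print(f"Pedigree: {g_ped.n_individuals} offspring, {n_fs} full-sib and "
          f"{n_hs} half-sib pairs, {g_ped.n_loci} loci")

    svy_cfg = SurveySimConfig(species="simfish", seed=SEED)
    table, svy_truth = simulate_survey(svy_cfg)
    write_survey_csv(table, SIM / "survey.csv")
    save_truth(svy_truth, SIM / "survey_truth.json")
    print(f"Survey: {len(table)} transects over {len(svy_cfg.years)} years "
          f"({table.df.groupby('stratum').size().to_dict()})")

    print(f"\nbundle written under {SIM}")


if __name__ == "__main__":
    main()
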