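# atollpop

Census and effective population size estimation for small, closed reef-fish
populations — from visual transect surveys on one side and RAD-seq SNP
matrices on the other.

Isolated atolls with endemic fishes are one of the few marine settings where
a census estimate of population size (N) can be compared head-on with
genetic estimates of effective size (Ne): the habitat is small enough to map,
and the population is closed, so both numbers describe the same fish. This
package implements that comparison for the worked example of two endemics of
Clipperton Atoll — an angelfish (*Holacanthus limbaughi*, ~35 genetic
samples) and a damselfish (*Stegastes baldwini*, ~24) — and ships simulators
with known ground truth so every stage can be validated at desk scale.

## What it computes

**Census size.** Per-transect counts become densities D (ind ha⁻¹); each
survey year's population size is N_y = D_y · A_eff, where
A_eff = A_shallow + φ·A_deep is the planar reef habitat with the deep
(50–100 m) stratum discounted by a per-species factor φ; the reported N is
the harmonic mean of the N_y (drift in a fluctuating population is governed
by the smallest yearly sizes). A linear-vs-exponential density trend can be
compared by AICc.

**Genetic diversity.** Observed/expected heterozygosity per SNP (unbiased
2n/(2n−1) correction), polymorphic-locus fraction, and per-site nucleotide
diversity π = Σ_sites 2n/(2n−1)·2p̂(1−p̂) / (total sequenced sites), the
per-nucleotide convention under which π ≈ 10⁻³ coexists with per-SNP
heterozygosity ≈ 0.05.

**Kinship.** Loiselle co-ancestry for every pair,
k_ij = [Σ_l (x_il−p̄_l)(x_jl−p̄_l) + Σ_l p̄_l(1−p̄_l)/(n_l−1)] / Σ_l p̄_l(1−p̄_l),
binned into nearly-identical / full-sib / half-sib / quarter-sib classes
(expectations 0.5, 0.25, 0.125, 0.0625), with relatedness networks and a
robustness re-analysis that strips apparent full sibs and recomputes
diversity.

**Effective size.** Two single-sample routes: (i) the linkage-disequilibrium
method — Burrows' composite Δ̂ between unphased, unlinked locus pairs,
r̄² averaged with per-pair sample-size weights, the sampling expectation
(1/S + 3.19/S² for S ≥ 30) subtracted, and the remainder inverted through
N̂e = (1/3 + √(1/9 − 2.76 r²′))/(2 r²′), with +∞ when the LD signal is
within sampling noise; (ii) mutation–drift equilibrium, Ne = π/(4 μ T) over
a grid of per-site-per-year mutation rates μ times generation time T.

**Simulators.** A forward Wright–Fisher model (true Ne known by
construction), a pedigree generator (true relationship labels), and a
Poisson transect-survey generator (true densities) give every estimator a
truth set.

## Worked example

`analysis/` holds the numbered drivers. The first one runs the census chain
on the published yearly densities and habitat areas (2.838 km² of reef to
50 m, a further 2.287 km² to 100 m; φ = 1 for the angelfish, φ = 0.2 for
the damselfish):

```
$ python analysis/01_census_population_size.py
H. limbaughi:
  1998:    61.0 ind/ha -> N = 31,262
  2005:   168.0 ind/ha -> N = 86,100
  2010:   190.0 ind/ha -> N = 97,375
  2016:   237.0 ind/ha -> N = 121,462
  mean density               164.0 ind/ha
  harmonic mean density      125.7 ind/ha
  N (0-50 m)                35,666
  N (0-100 m)               64,408
...
damselfish / angelfish mean-density ratio: 18.7
```

i.e. roughly 36,000 angelfish over the 0–50 m reef, rising to ~64,000 when
the deep habitat is included, and a damselfish population an order of
magnitude larger (~487,000 / ~565,000). Driver 05 adds the genetic side:

```
$ python analysis/05_effective_population_size.py
LD-Ne recovery, true Ne = 100 (20 replicates): median 151, IQR [110, 189], ...
H. limbaughi: pi = 0.0009, T = 4.1 y
  pi-based Ne: 5,488 (mu=1e-8/yr) to 54,878 (mu=1e-9/yr)
  Ne/N (pi-based, over N to 100 m): 0.085 - 0.852
```

so the π-based Ne sits within an order of magnitude of the census N
(Ne/N up to ~0.85 for the angelfish and ~0.14 for the damselfish) — high
for a marine fish, as expected for a small, closed population. Drivers
02–04 generate the simulated bundle and validate density recovery, trend
selection, kinship binning (mean Loiselle k over true full sibs 0.252,
half sibs 0.125), and the sib-removal robustness check.

## Layout

```
src/atollpop/     library: popdata, census, diversity, kinship, ne, synth,
                  pipeline, study
analysis/         numbered narrative drivers (write tables to results/)
tests/            pytest suite, including estimator-recovery checks
scripts/          acceptance.py
docs/methods.md   models, conventions, numerical choices, limitations
```
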