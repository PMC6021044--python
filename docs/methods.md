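# Methods

This note records the models behind each stage, the conventions and
numerical choices that were genuinely open, and what the synthetic-data
validation does and does not establish.

## Census population size

A transect is a 50 m × 5 m swath (250 m², the default), counted from the
sea floor to the surface, coded into a shallow (6–12 m) or deep (20 m)
stratum. Density for a species/year is total count over total transect
area, converted to individuals per hectare (1 ha = 10⁴ m²); pooling across
transects therefore weights by area, not by transect.

Population size per year is density times effective habitat area
A_eff = A_shallow + φ·A_deep, areas in hectares (km² × 100). φ is the deep
(50–100 m) density as a fraction of shallow density and is per-species
configuration: 1.0 for a species observed at undiminished density to
~100 m, 0.2 for one that thins out five-fold below 50 m. The multi-year
estimate is the **harmonic mean** of the yearly sizes: in a fluctuating
population the long-term rate of drift is set by the small years, and the
harmonic mean is the standard effective summary. Because habitat is
constant across years, taking the harmonic mean over yearly N or over
yearly densities is equivalent up to the area factor; we compute it over
yearly N. The harmonic mean is undefined (domain error) for any
non-positive yearly value.

Density trends over years are compared by least squares with
AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1), k = 3 (two curve parameters
plus the error variance). The exponential model y = a·e^{bt} is fitted by
nonlinear least squares on the original scale — a log-linear fit would
down-weight the large recent years — with a log-linear start point. With
k = 3 the comparison needs at least five observations, so it applies to
per-transect or long survey series, not to four yearly means. A perfect
fit's RSS is floored at 10⁻³⁰⁰ to keep AICc finite; both models hit the
floor on constant data and tie.

## RAD read QC

Raw reads are truncated at the 3′ end to 92 bases, kept if the product of
per-base correctness probabilities Π(1 − 10^(−Q_i/10)) over those 92 bases
is ≥ 0.80, demultiplexed by exact match of the 6-bp barcode, and emitted as
the 80-bp tag after removing barcode plus 6-bp restriction-site residue
from the 5′ end. The quality rule is stated in the field as a "product of
quality scores"; the probability-of-correctness reading is the only
probabilistically coherent one (the product of error probabilities would be
astronomically small and monotone the wrong way), so that is what is
implemented. The product is computed in log space. Reads shorter than 92 bp
count as dropped; kept + dropped + unassigned always equals the input count.

## Genotype matrices and filtering

Genotypes are biallelic diploid SNP calls coded 0/1/2 as copies of the
designated alternate allele, −1 for missing. Every downstream statistic is
invariant under swapping which allele is "alternate" (tested as a property),
so the designation is a convention: VCF supplies it; for Genepop the minor
allele over the file is taken as alternate (ties to the larger allele
code), which means a write/read round trip through Genepop reproduces calls
exactly when the alternate is minor and up to the symmetric flip c → 2−c
otherwise — the format itself does not record the designation. Loci are
"unplaced": no physical map is assumed anywhere.

Locus filtering keeps loci with minor-allele frequency ≥ 0.05 (computed on
non-missing calls — the pairwise-available convention matching how
completeness-filtered genotype tables are analysed) and non-missing
fraction ≥ 0.8, both thresholds exposed. Filtering to an empty matrix is a
warning, not an error: stringent filters on low-diversity data can do that
legitimately.

## Diversity statistics

Per locus: Ho is the fraction of non-missing individuals that are
heterozygous; He = 2p̂(1−p̂) with the unbiased 2n/(2n−1) factor by default
(plain 2pq via flag), n the per-locus non-missing count. Means are reported
over polymorphic loci by default (the convention of standard
genotype-table software), with an all-loci flag.

π is per-nucleotide: the summed unbiased per-site heterozygosity of the
variant sites divided by the **total number of sequenced sites** — number
of assayed RAD tags times the 80-bp tag length — so monomorphic sites
dilute the denominator. This is the convention under which π ≈ 9×10⁻⁴ and
per-SNP He ≈ 0.05 describe the same data. A brute-force identity used as a
test oracle: per site, π equals the fraction of differing pairs among all
pairs of allele copies, a(m−a)/C(m,2) for a alternate copies of m.

The published polymorphic-locus percentages could not be reconciled with
the published per-individual locus and polymorphic-locus counts (6.66% vs
4210/49,454 = 8.51% for the angelfish); the denominator used by the
original locus-assembly software is not recoverable. `polymorphic_fraction`
therefore takes the assayed-locus denominator as an explicit argument.

## Loiselle kinship and sibship bins

k_ij = [Σ_l (x_il − p̄_l)(x_jl − p̄_l) + Σ_l p̄_l(1−p̄_l)/(n_l−1)] /
Σ_l p̄_l(1−p̄_l), with x the individual allele frequency (0, ½, 1), p̄_l and
n_l from the **full data set** (kinship is relative to the sample), loci
combined by summing numerators and denominators separately (stable for
rare alleles), and pairwise deletion of missing calls: each pair's sums run
over the loci typed in both members, while p̄_l and n_l stay full-sample.
Pairs sharing no usable locus are flagged undefined. Monomorphic loci and
loci with n_l < 2 drop out identically.

Expectations under the pedigree simulator: self ≈ (1+F)/2 ≈ 0.5 outbred,
full sib 0.25, half sib 0.125 — all recovered within ±0.005 at the default
simulation size. One algebraic subtlety is documented here because it is
easy to get wrong: relative to sample frequencies the mean off-diagonal
kinship among unrelated individuals is **+1/(2n)**, not 0 and not negative
— deviations from the sample mean force the cross-term average to −pq/(2n),
and the small-sample correction adds +pq/(n−1). The property test asserts
this derived value.

Bins close the rounding gaps of the conventional printed thresholds into
contiguous lower-exclusive/upper-inclusive intervals: unrelated ≤ 0.047 <
quarter-sib ≤ 0.09375 < half-sib ≤ 0.1875 < full-sib ≤ 0.375 <
nearly-identical, with k ≥ 0.57 still binned nearly-identical but flagged
(beyond the nominal duplicate range). Comparison counts include self-pairs
— n(n+1)/2, the bookkeeping under which 35 individuals give 630
comparisons and per-bin percentages sum to 100 — and self-pairs of outbred
individuals naturally land in the nearly-identical bin.

The relatedness network at a level joins every off-diagonal pair at that
bin or closer; isolated individuals count as singleton components. The
sib-removal re-analysis greedily removes the individual in the most
full-sib-or-closer pairs (ties by sample order) until none remain, refuses
if fewer than two individuals would survive, and reports diversity deltas;
in a low-diversity population whose "sibs" are artifacts of genome-wide
allele sharing the deltas are near zero, which is the signature the
re-analysis is designed to detect.

## Effective population size

**LD method.** Burrows' composite disequilibrium needs no phasing:
Δ̂ = sample covariance (n−1 denominator) of the two genotype-code columns
divided by 2. It is normalised by the composite allele-frequency variances
π_A = p(1−p) + D_A — half the genotype-code variance, absorbing any
Hardy–Weinberg departure — so r² is exactly the squared Pearson correlation
of genotype codes (identically-typed loci give r² = 1; at HW proportions
π_A reduces to p(1−p)). All moments use the individuals co-typed at both
loci; per-pair sample sizes weight the average r̄² (the missing-data
handling), and the harmonic-mean S enters the bias correction. The
sampling expectation subtracted from r̄² and the inversion to Ne follow the
two calibrated regimes: S ≥ 30, E[r²_s] = 1/S + 3.19/S² and
N̂e = (1/3 + √(1/9 − 2.76 r²′))/(2 r²′); S < 30,
E[r²_s] = 0.0018 + 0.907/S + 4.44/S² with the matching 0.308/2.08
coefficients. Random mating is the default; monogamy coefficients are
available. r²′ ≤ 0 (or a negative discriminant) yields +∞ — a sample whose
LD is fully explained by sampling noise carries no drift signal, and +∞ is
the honest report, serialised as the literal "inf" token. Locus pairs with
r² > 0.5 are counted as putatively physically linked and retained by
default (an exclusion flag exists); the parametric CI treats
n_pairs·r̄²/E[r̄²] as χ² with n_pairs degrees of freedom — pairs sharing
loci are positively correlated, so the interval is anti-conservative, and
the upper Ne bound is frequently +∞.

**π method.** Ne = π/(4 μ T): μ is a per-site per-year rate (10⁻⁹–10⁻⁸
for fish RAD sequence), multiplied by generation time T in years to give
the per-generation rate — the only reading under which π = 9×10⁻⁴ and
T = 4.1 y give Ne ≈ 5.5×10³ at μ = 10⁻⁸. The estimate is reported as the
range over the μ grid (high bound from the low rate) with a point at the
geometric-mean rate. The published table's damselfish π-Ne row is a
factor of 10 above this formula (and the "14×" between-species ratio
follows that row); the formula is implemented as stated and the
discrepancy left as a property of the source table.

Ne/N ratios are elementwise over the Ne bounds; +∞ propagates.

## Synthetic data

The Wright–Fisher simulator is the ideal population itself — N diploids,
discrete generations, random mating with replacement (selfing allowed, as
in the ideal model), free recombination, optional symmetric two-allele
mutation — so its census N *is* its Ne, which is what makes it a truth set
for the LD method. Defaults mirror the recovery condition exercised in the
tests: N = 100, 50 sampled, 200 unlinked loci, initial frequencies
U(0.05, 0.95), 60 generations of burn-in — enough for genotypic LD to
reach drift–recombination equilibrium (unlinked LD halves each generation)
while longer runs would only lose loci to fixation. Expected
heterozygosity decays as (1 − 1/(2N))^t without mutation, neutral fixation
probability equals initial frequency, and at mutation–drift equilibrium
E[π] ≈ 4Nμ for small θ (the symmetric two-allele model depresses this by
1/(1+2θ), which is why the equilibrium test uses a small θ and a 20%
band).

The pedigree generator draws unrelated founders at per-locus frequencies
U(0.1, 0.9) and produces, per family, two full-sib offspring plus one
half-sib offspring by Mendelian transmission (100 families by default,
1000 loci), emitting the true label for every pair. The survey generator
reproduces the study layout — 73 transects of 250 m², 47 shallow and 26
deep, spread over four expedition years — with Poisson counts around
stratum densities (defaults ~160/80 ind ha⁻¹, an angelfish-like scale) and
optional linear or exponential year trends.

What passing these validations shows: the estimators recover truth under
their own model assumptions (unlinked loci, random mating, closed
population, independent Poisson counts). What they do not show: robustness
to physical linkage, population structure, overlapping generations,
non-random transect placement, or observer error — none of which the
generators emulate. All generators are bit-reproducible from their config
seed; truth records are JSON sidecars so the data files stay standard.

## Numerical conventions

Harmonic means and quality products are computed via reciprocals/logs in
float64; kinship and r² matrices enforce exact symmetry by averaging with
their transpose; degenerate inputs (empty filters, fully missing loci,
monomorphic pairs, pairs with no shared loci) are excluded with flags
rather than propagating NaN; ties in the sib-removal greedy cover break by
sample order so results are order-stable; all randomness flows from a
single integer seed per generator config.

## Known limitations

Genepop round trips are exact only up to the allele-coding convention (see
above). The LD-method CI understates uncertainty by design of the
parametric approximation. π-based Ne inherits the full order-of-magnitude
uncertainty of μ. The census chain treats habitat area and the deep-density
factor as known configuration; their error is not propagated. AICc values
are comparable only within a dataset, and the trend comparison needs ≥ 5
time points.
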