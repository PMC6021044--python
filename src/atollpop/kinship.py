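"""Pairwise Loiselle co-ancestry, sibship binning, relatedness networks,
and the sib-removal robustness re-analysis.

The Loiselle estimator weights each locus by its allele-frequency variance,
which keeps rare alleles from dominating, and includes a small-sample term
p(1-p)/(n-1) in the numerator. Expectations: ~0.5 for an individual with
itself (outbred), 0.25 for full sibs, 0.125 for half sibs, and slightly
below 0 for unrelated pairs when frequencies come from the sample itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import networkx as nx
import numpy as np

from .diversity import DiversityReport, diversity_report
from .popdata import MISSING, DomainError, GenotypeMatrix, locus_allele_stats

#: Sibship bins, closest first.
BIN_ORDER = ("nearly_identical", "full_sib", "half_sib", "quarter_sib", "unrelated")


@dataclass(frozen=True)
class KinBinScheme:
    """Kinship bin edges as contiguous half-open intervals (lower-exclusive,
    upper-inclusive), closing the rounding gaps of the conventional
    printed bounds (0.374 -> 0.375 and so on).

    Anything above ``quarter_sib_min`` up to ``full_sib_max`` maps to the
    named bins; k > ``full_sib_max`` is nearly_identical (values at or above
    ``identical_flag`` — beyond the nominal duplicate range — are flagged
    but still binned there).
    """

    quarter_sib_min: float = 0.047
    half_sib_min: float = 0.09375
    full_sib_min: float = 0.1875
    full_sib_max: float = 0.375
    identical_flag: float = 0.57

    def classify(self, k: float) -> str:
        if np.isnan(k):
            return "undefined"
        if k > self.full_sib_max:
            return "nearly_identical"
        if k > self.full_sib_min:
            return "full_sib"
        if k > self.half_sib_min:
            return "half_sib"
        if k > self.quarter_sib_min:
            return "quarter_sib"
        return "unrelated"


@dataclass
class KinshipResult:
    """Symmetric kinship matrix with (optionally) its sibship binning.

    ``n_comparisons`` counts unordered pairs including self-pairs,
    n(n+1)/2 — the denominator under which the per-bin percentages sum to
    100. Self-pairs of an outbred individual land in nearly_identical.
    """

    individuals: list[str]
    k: np.ndarray
    bins: dict[tuple[int, int], str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    flagged_pairs: list[tuple[int, int]] = field(default_factory=list)
    undefined_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_comparisons(self) -> int:
        n = len(self.individuals)
        return n * (n + 1) // 2


def loiselle_matrix(g: GenotypeMatrix) -> KinshipResult:
    """Loiselle kinship for every pair of individuals (self-pairs included).

    k_ij = [sum_l (x_il - p_l)(x_jl - p_l) + sum_l p_l(1-p_l)/(n_l - 1)]
           / sum_l p_l(1-p_l)

    where x is the individual allele frequency (0, 1/2, 1), p_l the
    alternate-allele frequency over the full data set, n_l the non-missing
    sample size at locus l, and each pair's sums run over the loci typed in
    both members (pairwise deletion). Numerators and denominators are summed
    across loci before dividing (exact multilocus weighting, not a mean of
    per-locus ratios). Pairs sharing no usable locus get NaN and are
    reported in ``undefined_pairs``.
    """
    if g.n_individuals < 2:
        raise DomainError("kinship needs at least two individuals")
    p, n_l, _ = locus_allele_stats(g)
    pq = p * (1.0 - p)
    usable = ~np.isnan(p) & (pq > 0) & (n_l >= 2)
    if not usable.any():
        raise DomainError("kinship needs at least one polymorphic locus")

    calls = g.calls[:, usable].astype(float)
    present = (calls != MISSING).astype(float)
    x = np.where(present > 0, calls / 2.0, 0.0)
    pu = p[usable]
    pqu = pq[usable]
    wu = pqu / (n_l[usable] - 1.0)

    dev = (x - pu) * present  # zero where missing
    cross = dev @ dev.T  # sum_l (x_i-p)(x_j-p) over co-typed loci
    co = present @ (present * wu[None, :]).T  # sum_l w_l over co-typed loci
    denom = present @ (present * pqu[None, :]).T
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(denom > 0, (cross + co) / denom, np.nan)
    k = (k + k.T) / 2.0  # enforce exact symmetry against float noise

    undefined = [
        (i, j)
        for i in range(g.n_individuals)
        for j in range(i, g.n_individuals)
        if denom[i, j] == 0
    ]
    return KinshipResult(individuals=list(g.individuals), k=k, undefined_pairs=undefined)


def classify_kinship(
    result: KinshipResult, scheme: KinBinScheme | None = None
) -> KinshipResult:
    """Assign every unordered pair (self-pairs included) to a sibship bin
    and tabulate per-bin counts and percentages of n(n+1)/2 comparisons."""
    scheme = scheme or KinBinScheme()
    if not np.allclose(result.k, result.k.T, equal_nan=True):
        raise ValueError("kinship matrix must be symmetric")
    n = len(result.individuals)
    bins: dict[tuple[int, int], str] = {}
    counts = {b: 0 for b in BIN_ORDER}
    counts["undefined"] = 0
    flagged: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i, n):
            label = scheme.classify(result.k[i, j])
            bins[(i, j)] = label
            counts[label] += 1
            if not np.isnan(result.k[i, j]) and result.k[i, j] >= scheme.identical_flag:
                flagged.append((i, j))
    total = result.n_comparisons
    result.bins = bins
    result.counts = counts
    result.percentages = {b: 100.0 * c / total for b, c in counts.items()}
    result.flagged_pairs = flagged
    return result


def _bin_at_or_closer(label: str, level: str) -> bool:
    if label not in BIN_ORDER:
        return False
    return BIN_ORDER.index(label) <= BIN_ORDER.index(level)


def kin_network(result: KinshipResult, level: str = "half_sib") -> dict:
    """Relatedness graph at a sibship level.

    An edge joins every off-diagonal pair whose bin is at ``level`` or any
    closer bin. Returns per-individual degree, the individuals with at
    least one such relationship, and the connected components (isolated
    individuals count as their own component).
    """
    if level not in BIN_ORDER[:-1]:
        raise ValueError(f"level must be one of {BIN_ORDER[:-1]}")
    if not result.bins:
        raise ValueError("classify_kinship must run before kin_network")
    G = nx.Graph()
    G.add_nodes_from(result.individuals)
    for (i, j), label in result.bins.items():
        if i != j and _bin_at_or_closer(label, level):
            G.add_edge(result.individuals[i], result.individuals[j])
    degree = dict(G.degree())
    connected = sorted(s for s, d in degree.items() if d >= 1)
    components = [sorted(c) for c in nx.connected_components(G)]
    components.sort(key=lambda c: (-len(c), c))
    return {
        "level": level,
        "degree": degree,
        "connected_individuals": connected,
        "n_connected": len(connected),
        "components": components,
        "graph": G,
    }


def drop_fullsibs_and_recompute(
    g: GenotypeMatrix,
    result: KinshipResult,
    assayed_loci: int | None = None,
    extra_stats: Callable[[GenotypeMatrix], Mapping[str, float]] | None = None,
) -> dict:
    """Robustness re-analysis: strip full-sib (or closer) pairs and compare.

    Greedily removes the individual participating in the most full-sib-or-
    closer off-diagonal pairs (ties broken by sample order) until none
    remain, then recomputes the diversity report (and any ``extra_stats``,
    e.g. an Ne estimate) on the reduced matrix. If apparent sibship merely
    reflects genome-wide allele sharing in a low-diversity population, the
    deltas are near zero.
    """
    if not result.bins:
        raise ValueError("classify_kinship must run before sib removal")
    keep = list(range(g.n_individuals))
    sib_pairs = {
        (i, j)
        for (i, j), label in result.bins.items()
        if i != j and _bin_at_or_closer(label, "full_sib")
    }
    removed: list[str] = []
    pairs = set(sib_pairs)
    while pairs:
        degree: dict[int, int] = {}
        for i, j in pairs:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
        victim = max(sorted(degree), key=lambda i: degree[i])
        if len(keep) - 1 < 2:
            raise DomainError("sib removal would leave fewer than two individuals")
        keep.remove(victim)
        removed.append(g.individuals[victim])
        pairs = {(i, j) for (i, j) in pairs if victim not in (i, j)}

    g_after = g.subset_individuals(keep)
    before = diversity_report(g, assayed_loci=assayed_loci)
    after = diversity_report(g_after, assayed_loci=assayed_loci)
    out = {
        "removed": removed,
        "n_sib_pairs": len(sib_pairs),
        "before": before,
        "after": after,
        "delta": _report_delta(before, after),
    }
    if extra_stats is not None:
        sb, sa = dict(extra_stats(g)), dict(extra_stats(g_after))
        out["extra_before"] = sb
        out["extra_after"] = sa
        out["extra_delta"] = {k: sa[k] - sb[k] for k in sb if k in sa}
    return out


def _report_delta(before: DiversityReport, after: DiversityReport) -> dict[str, float]:
    return {
        "obs_het": after.obs_het - before.obs_het,
        "exp_het": after.exp_het - before.exp_het,
        "pi_per_site": after.pi_per_site - before.pi_per_site,
        "polymorphic_fraction": after.polymorphic_fraction
        - before.polymorphic_fraction,
    }
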