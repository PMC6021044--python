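"""Loiselle kinship, sibship binning, relatedness networks, sib removal."""

import numpy as np
import pytest

import atollpop as ap
from atollpop.popdata import DomainError, MISSING

from conftest import make_matrix, random_matrix


def loiselle_loop(calls):
    """Independent per-locus-loop oracle for the Loiselle matrix."""
    calls = np.asarray(calls, dtype=float)
    n, L = calls.shape
    present = calls != MISSING
    p = np.array(
        [
            calls[present[:, l], l].sum() / (2 * present[:, l].sum())
            if present[:, l].any()
            else np.nan
            for l in range(L)
        ]
    )
    nl = present.sum(axis=0)
    k = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            num = 0.0
            den = 0.0
            for l in range(L):
                if not (present[i, l] and present[j, l]):
                    continue
                pq = p[l] * (1 - p[l])
                if pq == 0 or nl[l] < 2:
                    continue
                xi, xj = calls[i, l] / 2, calls[j, l] / 2
                num += (xi - p[l]) * (xj - p[l]) + pq / (nl[l] - 1)
                den += pq
            if den > 0:
                k[i, j] = num / den
    return k


class TestLoiselleMatrix:
    def test_matches_per_locus_loop_oracle(self, rng):
        for _ in range(10):
            g = random_matrix(rng, n=5, L=10, missing_rate=0.2)
            try:
                got = ap.loiselle_matrix(g).k
            except DomainError:
                continue  # no polymorphic locus in this draw
            want = loiselle_loop(g.calls)
            np.testing.assert_allclose(got, want, atol=1e-12, equal_nan=True)

    def test_symmetric_and_permutation_equivariant(self, rng):
        g = random_matrix(rng, n=8, L=25, missing_rate=0.1)
        k = ap.loiselle_matrix(g).k
        np.testing.assert_array_equal(k, k.T)
        perm = list(rng.permutation(8))
        k_perm = ap.loiselle_matrix(g.subset_individuals(perm)).k
        np.testing.assert_allclose(k_perm, k[np.ix_(perm, perm)], atol=1e-12)

    def test_duplicate_individual_nearly_identical(self):
        g, truth = ap.simulate_pedigree_genotypes(
            ap.PedigreeConfig(n_families=20, duplicate_first=True, seed=5)
        )
        kr = ap.classify_kinship(ap.loiselle_matrix(g))
        idx = {s: i for i, s in enumerate(g.individuals)}
        (a, b) = next(p for p, l in truth["labels"].items() if l == "duplicate")
        assert kr.bins[tuple(sorted((idx[a], idx[b])))] == "nearly_identical"

    def test_pedigree_full_and_half_sib_means(self):
        g, truth = ap.simulate_pedigree_genotypes(ap.PedigreeConfig(seed=11))
        k = ap.loiselle_matrix(g).k
        idx = {s: i for i, s in enumerate(g.individuals)}
        means = {}
        for label in ("full_sib", "half_sib"):
            vals = [
                k[idx[a], idx[b]] for (a, b), l in truth["labels"].items() if l == label
            ]
            means[label] = float(np.mean(vals))
        assert means["full_sib"] == pytest.approx(0.25, abs=0.02)
        assert means["half_sib"] == pytest.approx(0.125, abs=0.02)

    def test_unrelated_mean_near_zero(self):
        """Relative to sample frequencies the off-diagonal mean is +1/(2n),
        not 0: the cross-term bias is -pq/(2n) (deviations from the sample
        mean sum to zero) and the small-sample correction adds +pq/(n-1),
        leaving ~ +pq/(2n). Assert the mean sits within 1/(n-1) of zero and
        matches that derivation."""
        g, _ = ap.simulate_pedigree_genotypes(
            ap.PedigreeConfig(
                n_families=50, n_fullsib_offspring=0, n_halfsib_offspring=0,
                include_founders=True, L=3000, seed=7,
            )
        )
        n = g.n_individuals
        k = ap.loiselle_matrix(g).k
        off = k[np.triu_indices(n, k=1)]
        assert abs(off.mean()) < 1.0 / (n - 1)
        assert off.mean() == pytest.approx(1.0 / (2 * (n - 1)), abs=2e-3)

    def test_self_kinship_near_half_when_outbred(self):
        g, _ = ap.simulate_pedigree_genotypes(
            ap.PedigreeConfig(n_families=40, n_fullsib_offspring=0,
                              n_halfsib_offspring=0, include_founders=True, seed=3)
        )
        diag = np.diag(ap.loiselle_matrix(g).k)
        assert diag.mean() == pytest.approx(0.5, abs=0.02)

    def test_needs_two_individuals_and_polymorphism(self):
        with pytest.raises(DomainError):
            ap.loiselle_matrix(make_matrix(np.array([[0, 1]], dtype=np.int8)))
        with pytest.raises(DomainError):
            ap.loiselle_matrix(make_matrix(np.zeros((3, 4), dtype=np.int8)))


class TestClassifyKinship:
    @pytest.mark.parametrize(
        "k,label",
        [
            (0.4, "nearly_identical"),
            (0.2, "full_sib"),
            (0.1, "half_sib"),
            (0.05, "quarter_sib"),
            (0.01, "unrelated"),
            (-0.05, "unrelated"),
        ],
    )
    def test_bin_boundaries(self, k, label):
        assert ap.KinBinScheme().classify(k) == label

    def test_comparison_count_includes_self_pairs(self):
        n = 35
        kr = ap.KinshipResult(individuals=[f"i{j}" for j in range(n)],
                              k=np.zeros((n, n)))
        assert kr.n_comparisons == 630

    def test_percentages_sum_to_100(self, rng):
        g = random_matrix(rng, n=10, L=40, missing_rate=0.05)
        kr = ap.classify_kinship(ap.loiselle_matrix(g))
        assert sum(kr.percentages.values()) == pytest.approx(100.0)

    def test_sib_counts_over_630_comparisons(self):
        """88 pairs at quarter-sib-or-closer out of 35 individuals is
        88/630 = 13.97% of comparisons."""
        n = 35
        k = np.full((n, n), 0.01)
        np.fill_diagonal(k, 0.5)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        for i, j in pairs[:88]:
            k[i, j] = k[j, i] = 0.06  # quarter_sib
        kr = ap.classify_kinship(
            ap.KinshipResult(individuals=[f"i{j}" for j in range(n)], k=k)
        )
        assert kr.counts["quarter_sib"] == 88
        assert kr.percentages["quarter_sib"] == pytest.approx(13.97, abs=0.005)

    def test_extreme_k_flagged_but_binned(self):
        k = np.array([[0.5, 0.8], [0.8, 0.5]])
        kr = ap.classify_kinship(ap.KinshipResult(individuals=["a", "b"], k=k))
        assert kr.bins[(0, 1)] == "nearly_identical"
        assert (0, 1) in kr.flagged_pairs


class TestKinNetwork:
    @staticmethod
    def result_from_bins(n, bin_pairs):
        k = np.full((n, n), 0.0)
        np.fill_diagonal(k, 0.5)
        values = {"full_sib": 0.25, "half_sib": 0.125, "quarter_sib": 0.06}
        for (i, j), label in bin_pairs.items():
            k[i, j] = k[j, i] = values[label]
        return ap.classify_kinship(
            ap.KinshipResult(individuals=[f"i{j}" for j in range(n)], k=k)
        )

    def test_no_edges_means_no_connected_individuals(self):
        kr = self.result_from_bins(5, {})
        net = ap.kin_network(kr, "half_sib")
        assert net["n_connected"] == 0
        assert len(net["components"]) == 5  # all singletons

    def test_two_disjoint_families_two_components(self):
        kr = self.result_from_bins(6, {(0, 1): "full_sib", (2, 3): "full_sib"})
        net = ap.kin_network(kr, "full_sib")
        assert net["n_connected"] == 4
        comps = [c for c in net["components"] if len(c) > 1]
        assert len(comps) == 2

    def test_closer_bins_count_at_lower_level(self):
        kr = self.result_from_bins(4, {(0, 1): "full_sib", (1, 2): "quarter_sib"})
        net = ap.kin_network(kr, "quarter_sib")
        assert net["n_connected"] == 3
        assert sorted(net["components"], key=len)[-1] == ["i0", "i1", "i2"]

    def test_complete_graph_single_component(self):
        pairs = {(i, j): "quarter_sib" for i in range(5) for j in range(i + 1, 5)}
        kr = self.result_from_bins(5, pairs)
        net = ap.kin_network(kr, "quarter_sib")
        assert net["n_connected"] == 5
        assert len(net["components"]) == 1


class TestSibRemoval:
    @staticmethod
    def crafted_bins(g, sib_pairs):
        """KinshipResult over g's individuals with exactly the given
        off-diagonal pairs at full-sib kinship."""
        n = g.n_individuals
        k = np.full((n, n), 0.0)
        np.fill_diagonal(k, 0.5)
        for i, j in sib_pairs:
            k[i, j] = k[j, i] = 0.25
        return ap.classify_kinship(
            ap.KinshipResult(individuals=list(g.individuals), k=k)
        )

    def test_no_sibs_leaves_report_unchanged(self, rng):
        g = random_matrix(rng, n=10, L=60, missing_rate=0.0)
        out = ap.drop_fullsibs_and_recompute(g, self.crafted_bins(g, []))
        assert out["removed"] == []
        assert out["before"] == out["after"]

    def test_one_fullsib_pair_removes_exactly_one(self, rng):
        g = random_matrix(rng, n=10, L=60, missing_rate=0.0)
        out = ap.drop_fullsibs_and_recompute(g, self.crafted_bins(g, [(2, 5)]))
        assert out["removed"] == ["ind2"]  # tie on degree -> sample order

    def test_hub_individual_removed_first(self, rng):
        g = random_matrix(rng, n=10, L=60, missing_rate=0.0)
        out = ap.drop_fullsibs_and_recompute(
            g, self.crafted_bins(g, [(3, 4), (3, 7), (3, 9)])
        )
        assert out["removed"] == ["ind3"]  # covers all three pairs at once

    def test_refuses_to_empty_the_sample(self, rng):
        g = random_matrix(rng, n=2, L=60, missing_rate=0.0)
        with pytest.raises(DomainError):
            ap.drop_fullsibs_and_recompute(g, self.crafted_bins(g, [(0, 1)]))

    def test_apparent_sibs_in_low_diversity_population(self):
        """In a drifted, low-diversity population apparent full sibs arise
        from genome-wide allele sharing; removing them barely moves He."""
        g, _ = ap.simulate_wf_population(
            ap.WFConfig(N_true=30, generations=120, L=400, init_freq=0.5,
                        sample_size=30, seed=9)
        )
        gf = ap.filter_loci(g, maf_min=0.05, completeness_min=0.0)
        kr = ap.classify_kinship(ap.loiselle_matrix(gf))
        out = ap.drop_fullsibs_and_recompute(gf, kr)
        he_before = out["before"].exp_het
        assert he_before > 0
        assert abs(out["delta"]["exp_het"]) / he_before < 0.05
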