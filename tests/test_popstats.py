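"""Diversity, differentiation, and marker-comparison statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from cryptodelim import popstats
from cryptodelim.geno_io import SNP, SSR, GenotypeDataset, Locus, ValidationError
from cryptodelim.popstats import LocusFrequencies


def _freqs(per_group_counts, locus_names=None):
    groups = sorted(per_group_counts)
    n_loci = len(next(iter(per_group_counts.values())))
    names = locus_names or [f"l{i}" for i in range(n_loci)]
    return LocusFrequencies(groups, names, per_group_counts)


def _dataset(calls_by_group, marker=SSR):
    """calls_by_group: {group: [[call, ...] per individual]}"""
    individuals, calls, groups = [], [], {}
    n_loci = len(next(iter(calls_by_group.values()))[0])
    for grp in sorted(calls_by_group):
        for i, row in enumerate(calls_by_group[grp]):
            ind = f"{grp}_{i}"
            individuals.append(ind)
            groups[ind] = grp
            calls.append(row)
    loci = [Locus(f"l{i}", marker) for i in range(n_loci)]
    return GenotypeDataset(individuals, loci, calls, groups)


class TestGeneDiversity:
    def test_two_equifrequent_alleles(self):
        f = _freqs({"g": [{1: 5, 2: 5}]})
        assert popstats.gene_diversity(f)["g"] == pytest.approx(10 / 9 * 0.5, abs=1e-12)

    def test_monomorphic_locus_contributes_zero(self):
        f = _freqs({"g": [{1: 8}, {1: 4, 2: 4}]})
        expected = (0.0 + 8 / 7 * 0.5) / 2
        assert popstats.gene_diversity(f)["g"] == pytest.approx(expected)

    def test_all_singleton_alleles_give_exactly_one(self):
        # n alleles in n copies: (n/(n-1)) (1 - 1/n) = 1
        f = _freqs({"g": [{a: 1 for a in range(6)}]})
        assert popstats.gene_diversity(f)["g"] == pytest.approx(1.0, abs=1e-12)


class TestEffectiveAlleles:
    @pytest.mark.parametrize(
        "counts,expected",
        [({1: 5, 2: 5}, 2.0), ({1: 9}, 1.0), ({1: 7, 2: 2, 3: 1}, 1 / 0.54)],
    )
    def test_known_values(self, counts, expected):
        f = _freqs({"g": [counts]})
        assert popstats.effective_alleles(f)["g"] == pytest.approx(expected, abs=1e-4)


def _richness_by_enumeration(counts, k):
    """Oracle: mean distinct-allele count over all C(n, k) subsamples."""
    copies = [a for a, c in counts.items() for _ in range(c)]
    subs = list(itertools.combinations(range(len(copies)), k))
    return np.mean([len({copies[i] for i in idx}) for idx in subs])


class TestAllelicRichness:
    def test_small_case_matches_exhaustive_enumeration(self):
        counts = {1: 2, 2: 1, 3: 1}
        f = _freqs({"g": [counts]})
        ar, k = popstats.allelic_richness(f, 2)
        assert k == 2
        assert ar["g"] == pytest.approx(5 / 6 + 0.5 + 0.5, abs=1e-12)
        assert ar["g"] == pytest.approx(_richness_by_enumeration(counts, 2), abs=1e-12)

    def test_k_equals_n_returns_observed_allele_count(self):
        counts = {1: 3, 2: 2, 3: 1}
        f = _freqs({"g": [counts]})
        ar, _ = popstats.allelic_richness(f, 6)
        assert ar["g"] == pytest.approx(3.0, abs=1e-12)

    def test_monomorphic_locus_is_one_for_any_k(self):
        f = _freqs({"g": [{4: 10}]})
        for k in (1, 3, 10):
            assert popstats.allelic_richness(f, k)[0]["g"] == pytest.approx(1.0)

    def test_monotone_in_k_up_to_observed_count(self):
        counts = {1: 6, 2: 3, 3: 1}
        f = _freqs({"g": [counts]})
        values = [popstats.allelic_richness(f, k)[0]["g"] for k in range(1, 11)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(3.0)

    def test_k_exceeding_copies_rejected(self):
        f = _freqs({"g": [{1: 4}]})
        with pytest.raises(ValidationError):
            popstats.allelic_richness(f, 5)

    def test_default_uses_per_locus_minimum_over_groups(self):
        f = _freqs({"a": [{1: 4, 2: 2}], "b": [{1: 2}]})
        ar, k = popstats.allelic_richness(f)
        assert k == 2
        assert ar["a"] == pytest.approx(_richness_by_enumeration({1: 4, 2: 2}, 2))


class TestPropPolymorphic:
    def test_limits(self):
        fixed = _freqs({"g": [{1: 4}, {2: 4}]})
        poly = _freqs({"g": [{1: 2, 2: 2}, {1: 3, 3: 1}]})
        assert popstats.prop_polymorphic(fixed)["g"] == 0.0
        assert popstats.prop_polymorphic(poly)["g"] == 1.0


def _theta_textbook(g, groups, pair):
    """Independent coding of the two-population theta estimator, written
    directly from the variance-component formulas (per-locus/per-allele
    a, b, c; ratio of sums).  Serves as an oracle for fst_wc."""
    pos = {ind: i for i, ind in enumerate(g.individuals)}
    by_group = {p: [i for i in g.individuals if groups[i] == p] for p in pair}
    r = 2
    num = den = 0.0
    for l in range(g.n_loci):
        data = {}
        for p in pair:
            calls = [g.calls[pos[i]][l] for i in by_group[p]]
            data[p] = [c for c in calls if c is not None]
        ns = {p: len(data[p]) for p in pair}
        if min(ns.values()) < 2:
            continue
        alleles = {a for p in pair for c in data[p] for a in c}
        if len(alleles) < 2:
            continue
        nbar = sum(ns.values()) / r
        nc = (r * nbar - sum(n * n for n in ns.values()) / (r * nbar)) / (r - 1)
        for allele in alleles:
            p_i, h_i = [], []
            for p in pair:
                copies = [x for c in data[p] for x in c]
                p_i.append(copies.count(allele) / len(copies))
                h_i.append(
                    sum(1 for c in data[p] if allele in c and c[0] != c[1]) / ns[p]
                )
            n_i = [ns[p] for p in pair]
            pbar = sum(n * q for n, q in zip(n_i, p_i)) / (r * nbar)
            s2 = sum(n * (q - pbar) ** 2 for n, q in zip(n_i, p_i)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


class TestFstWC:
    def test_fixed_differences_give_theta_one(self):
        g = _dataset(
            {"x": [[(1, 1)]] * 5, "y": [[(2, 2)]] * 5}
        )
        assert popstats.fst_wc(g, pair=("x", "y")) == pytest.approx(1.0)

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(3)
        calls = {
            grp: [
                [
                    tuple(sorted(rng.integers(1, 5, size=2).tolist()))
                    for _ in range(6)
                ]
                for _ in range(10)
            ]
            for grp in ("x", "y")
        }
        g = _dataset(calls)
        groups = g.group_labels
        assert popstats.fst_wc(g, pair=("x", "y")) == pytest.approx(
            _theta_textbook(g, groups, ("x", "y")), abs=1e-12
        )

    def test_null_expectation_near_zero_under_panmixia(self):
        """A single random-mating pool split arbitrarily in two has theta ~ 0."""
        rng = np.random.default_rng(11)
        thetas = []
        for _ in range(200):
            freqs = rng.dirichlet(np.ones(4), size=8)  # 8 loci, 4 alleles
            calls = []
            for _ in range(100):
                calls.append(
                    [
                        tuple(sorted(rng.choice(4, size=2, p=freqs[l]) + 1))
                        for l in range(8)
                    ]
                )
            g = _dataset({"x": calls[:50], "y": calls[50:]})
            thetas.append(popstats.fst_wc(g, pair=("x", "y")))
        assert abs(np.mean(thetas)) < 0.01

    def test_monomorphic_everywhere_is_an_error(self):
        g = _dataset({"x": [[(1, 1)]] * 3, "y": [[(1, 1)]] * 3})
        with pytest.raises(ValidationError):
            popstats.fst_wc(g, pair=("x", "y"))


class TestNeiDs:
    def test_hand_evaluated_two_locus_example(self):
        counts = {
            "x": [{1: 6, 2: 4}, {1: 10}],
            "y": [{1: 2, 2: 8}, {1: 8, 3: 2}],
        }
        f = _freqs(counts)
        # unbiased J per locus: (n sum p^2 - 1)/(n - 1), n gene copies
        jx = [(10 * (0.6**2 + 0.4**2) - 1) / 9, (10 * 1.0 - 1) / 9]
        jy = [(10 * (0.2**2 + 0.8**2) - 1) / 9, (10 * (0.8**2 + 0.2**2) - 1) / 9]
        jxy = [0.6 * 0.2 + 0.4 * 0.8, 1.0 * 0.8]
        expected = -math.log(np.mean(jxy) / math.sqrt(np.mean(jx) * np.mean(jy)))
        assert popstats.nei_ds(f, ("x", "y")) == pytest.approx(expected, abs=1e-12)

    def test_disjoint_allele_sets_give_infinity(self):
        f = _freqs({"x": [{1: 10}], "y": [{2: 10}]})
        assert popstats.nei_ds(f, ("x", "y")) == float("inf")

    def test_identical_large_samples_give_near_zero(self):
        rng = np.random.default_rng(5)
        ds = []
        for _ in range(20):
            p = rng.dirichlet(np.ones(5))
            counts = []
            for _ in range(2):
                draw = rng.multinomial(1000, p)
                counts.append({a + 1: int(c) for a, c in enumerate(draw) if c})
            f = _freqs({"x": [counts[0]], "y": [counts[1]]})
            ds.append(popstats.nei_ds(f, ("x", "y")))
        assert np.mean(np.abs(ds)) < 0.01

    def test_self_distance_is_exactly_zero(self):
        f = _freqs({"x": [{1: 6, 2: 4}], "y": [{1: 6, 2: 4}]})
        assert popstats.nei_ds(f, ("x", "x")) == 0.0
        # two samples that merely *look* identical keep the unbiased
        # correction, which may legitimately go slightly negative
        assert popstats.nei_ds(f, ("x", "y")) < 0.05


class TestDeltaMuSq:
    def test_single_locus_mean_difference(self):
        g = _dataset({"x": [[(10, 10)]] * 4, "y": [[(12, 12)]] * 4})
        assert popstats.delta_mu_sq(g, pair=("x", "y")) == pytest.approx(4.0)

    def test_identical_means_give_zero(self):
        g = _dataset({"x": [[(9, 11)]] * 4, "y": [[(10, 10)]] * 4})
        assert popstats.delta_mu_sq(g, pair=("x", "y")) == pytest.approx(0.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(9)
        calls = {
            grp: [
                [tuple(sorted(rng.integers(8, 15, size=2).tolist())) for _ in range(3)]
                for _ in range(6)
            ]
            for grp in ("x", "y")
        }
        g1 = _dataset(calls)
        shifted = {
            grp: [[(a + 7, b + 7) for a, b in row] for row in rows]
            for grp, rows in calls.items()
        }
        g2 = _dataset(shifted)
        assert popstats.delta_mu_sq(g1, pair=("x", "y")) == pytest.approx(
            popstats.delta_mu_sq(g2, pair=("x", "y")), abs=1e-12
        )

    def test_snp_loci_rejected(self):
        g = _dataset({"x": [[(1, 1)]] * 3, "y": [[(1, 2)]] * 3}, marker=SNP)
        with pytest.raises(ValidationError):
            popstats.delta_mu_sq(g, pair=("x", "y"), locus_indices=[0])


class TestPairwiseMatrix:
    def test_consistent_with_per_pair_calls_and_symmetric(self, scenario):
        g = scenario.genotypes
        groups = scenario.truth.cluster_labels
        mat = popstats.pairwise_matrix(g, groups, "DELTA_MU_SQ", SSR)
        assert np.allclose(mat.values, mat.values.T)
        for a, b in mat.pair_labels():
            assert mat.value(a, b) == pytest.approx(
                popstats.delta_mu_sq(g, groups, (a, b)), abs=1e-12
            )
        assert mat.global_value == pytest.approx(np.mean(mat.condensed()))

    def test_fst_global_is_multigroup_estimate(self, scenario):
        g = scenario.genotypes
        groups = scenario.truth.cluster_labels
        mat = popstats.pairwise_matrix(g, groups, "FST", SSR)
        assert mat.global_value == pytest.approx(
            popstats.fst_wc(g, groups, None, SSR), abs=1e-12
        )
        assert np.all(mat.condensed() > 0)


class TestWilcoxon:
    def test_fifteen_positive_differences(self):
        x = np.zeros(15)
        y = np.arange(1.0, 16.0)
        res = popstats.wilcoxon_signed_rank_z(x, y)
        assert res["W"] == 0.0
        assert res["abs_z"] == pytest.approx(60 / math.sqrt(1240 / 4), abs=1e-3)
        assert res["abs_z"] == pytest.approx(3.408, abs=1e-3)

    def test_agrees_with_scipy_normal_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = x + rng.normal(scale=0.5, size=20) + 0.3
        res = popstats.wilcoxon_signed_rank_z(x, y)
        ref = sps.wilcoxon(y, x, correction=False, mode="approx")
        z_ref = abs(sps.norm.ppf(ref.pvalue / 2))
        assert res["abs_z"] == pytest.approx(z_ref, abs=1e-6)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValidationError):
            popstats.wilcoxon_signed_rank_z(np.ones(8), np.ones(8))


class TestPearsonOLS:
    def test_identity_line(self):
        x = np.array([1.0, 2, 3, 4])
        res = popstats.pearson_ols(x, x)
        assert res["r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValidationError):
            popstats.pearson_ols([1, 1, 1], [1, 2, 3])
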