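"""Neighbour joining, bootstrap supports, and divergence dating."""

import itertools

import numpy as np
import pytest

from cryptodelim import phylo_time, popstats
from cryptodelim.geno_io import SSR, LabeledDistanceMatrix, ValidationError
from cryptodelim.phylo_time import divergence_time, nj_tree, tree_splits
from cryptodelim.synthetic_data import SimulationConfig, simulate_ssr_genotypes


def _ldm(labels, values, metric="DS"):
    return LabeledDistanceMatrix(list(labels), np.asarray(values, float), metric)


def _random_tree_matrix(rng, labels):
    """Random additive matrix: build a random binary tree with positive
    branch lengths, return its path-distance matrix and split set."""
    nodes = list(labels)
    graph = {}
    import networkx as nx

    g = nx.Graph()
    counter = itertools.count()
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        new = f"v{next(counter)}"
        g.add_edge(new, a, length=float(rng.uniform(0.1, 1.0)))
        g.add_edge(new, b, length=float(rng.uniform(0.1, 1.0)))
        nodes = [n for n in nodes if n not in (a, b)] + [new]
    n = len(labels)
    values = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            d = nx.shortest_path_length(g, labels[x], labels[y], weight="length")
            values[x, y] = values[y, x] = d
    return _ldm(labels, values), tree_splits(g, labels)


def _enumerate_topologies(labels):
    """All (2n-5)!! unrooted binary topologies by stepwise leaf insertion."""
    import networkx as nx

    a, b, c = labels[:3]
    base = nx.Graph()
    base.add_edges_from([("r0", a), ("r0", b), ("r0", c)])
    trees = [base]
    for idx, leaf in enumerate(labels[3:], start=1):
        nxt = []
        for t in trees:
            for u, v in list(t.edges):
                t2 = t.copy()
                t2.remove_edge(u, v)
                mid = f"m{idx}_{u}_{v}"
                t2.add_edges_from([(u, mid), (mid, v), (mid, leaf)])
                nxt.append(t2)
        trees = nxt
    return trees


def _fits_additively(topology, d: LabeledDistanceMatrix) -> bool:
    """Least-squares branch lengths for the topology; True iff residual ~ 0."""
    import networkx as nx

    edges = list(topology.edges)
    pairs = d.pair_labels()
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([d.value(a, b) for a, b in pairs])
    for row, (a, b) in enumerate(pairs):
        path = nx.shortest_path(topology, a, b)
        on_path = {frozenset(e) for e in zip(path, path[1:])}
        for col, e in enumerate(edges):
            if frozenset(e) in on_path:
                A[row, col] = 1.0
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.allclose(A @ sol, y, atol=1e-8)


class TestNJ:
    def test_three_taxa_closed_form(self):
        d = _ldm("ABC", [[0, 5, 9], [5, 0, 10], [9, 10, 0]])
        tree = nj_tree(d)
        center = next(n for n in tree.graph.nodes if n not in "ABC")
        assert tree.graph.edges[center, "A"]["length"] == pytest.approx(2.0)
        assert tree.graph.edges[center, "B"]["length"] == pytest.approx(3.0)
        assert tree.graph.edges[center, "C"]["length"] == pytest.approx(7.0)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        d = _ldm(
            "ABCD",
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
        )
        tree = nj_tree(d)
        assert tree.splits() == {frozenset({"A", "B"})}
        for a, b in itertools.combinations("ABCD", 2):
            assert tree.path_distance(a, b) == pytest.approx(d.value(a, b), abs=1e-12)

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValidationError):
            nj_tree(_ldm("AB", [[0, 1], [1, 0]]))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_additive_matrices_against_exhaustive_topology_search(self, n_taxa):
        """On additive input NJ must recover the unique fitting topology,
        verified against enumeration of all unrooted binary topologies."""
        rng = np.random.default_rng(100 + n_taxa)
        labels = [f"T{i}" for i in range(n_taxa)]
        topologies = _enumerate_topologies(labels)
        assert len(topologies) == {4: 3, 5: 15, 6: 105}[n_taxa]
        for _ in range(20):
            d, true_splits = _random_tree_matrix(rng, labels)
            tree = nj_tree(d)
            assert tree.splits() == true_splits
            for a, b in itertools.combinations(labels, 2):
                assert tree.path_distance(a, b) == pytest.approx(d.value(a, b), abs=1e-9)
            fitting = [t for t in topologies if _fits_additively(t, d)]
            assert len(fitting) == 1
            assert tree_splits(fitting[0], labels) == tree.splits()

    def test_matches_scikit_bio_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(17)
        labels = [f"T{i}" for i in range(6)]
        for _ in range(10):
            d, _ = _random_tree_matrix(rng, labels)
            ours = nj_tree(d).splits()
            sk_tree = skbio_nj(DistanceMatrix(d.values, labels))
            sk_splits = set()
            for node in sk_tree.non_tips():
                tips = frozenset(t.name for t in node.tips())
                if 2 <= len(tips) <= len(labels) - 2:
                    side = tips if len(tips) * 2 <= len(labels) else frozenset(set(labels) - tips)
                    if len(side) * 2 == len(labels):
                        side = frozenset(min(sorted(tips), sorted(set(labels) - tips)))
                    sk_splits.add(side)
            assert ours == sk_splits

    def test_ultrametric_matrix_reproduces_upgma_topology(self):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(23)
        for _ in range(10):
            # random ultrametric via average-linkage cophenetic distances
            pts = rng.normal(size=(6, 3))
            Z = hierarchy.average(
                squareform(np.linalg.norm(pts[:, None] - pts[None], axis=-1), checks=False)
            )
            coph = squareform(hierarchy.cophenet(Z))
            labels = [f"T{i}" for i in range(6)]
            d = _ldm(labels, coph)
            nj_splits = nj_tree(d).splits()
            # UPGMA splits from the linkage tree
            root, _ = hierarchy.to_tree(Z, rd=True)

            def clades(node, acc):
                if node.is_leaf():
                    return {node.id}
                left = clades(node.get_left(), acc)
                right = clades(node.get_right(), acc)
                tips = left | right
                acc.append(tips)
                return tips

            acc = []
            clades(root, acc)
            upgma_splits = set()
            for tips in acc:
                if 2 <= len(tips) <= 4:
                    side = frozenset(f"T{i}" for i in tips)
                    if len(side) > 3:
                        side = frozenset(set(labels) - set(side))
                    elif len(side) == 3:
                        other = frozenset(set(labels) - set(side))
                        side = frozenset(min(sorted(side), sorted(other)))
                    upgma_splits.add(side)
            assert nj_splits == upgma_splits


@pytest.fixture(scope="module")
def separated():
    """Two recently diverged populations plus two deep outgroups."""
    cfg = SimulationConfig(
        seed=5,
        populations=["A", "B", "C", "D"],
        sample_sizes={"A": 30, "B": 30, "C": 30, "D": 30},
        splits={
            "A": (None, 0.0),
            "B": ("A", 300.0),
            "C": ("A", 1500.0),
            "D": ("A", 3000.0),
        },
        n_e=200,
        ssr_loci=30,
    )
    return simulate_ssr_genotypes(cfg)


class TestBootstrap:

    def test_focal_bipartition_strongly_supported(self, separated):
        g, truth = separated
        tree = phylo_time.bootstrap_supports(
            g, truth.cluster_labels, metric="DS", B=500, seed=1, marker_type=SSR
        )
        supports = {tuple(sorted(s)): v for s, v in tree.supports.items()}
        assert supports[("A", "B")] >= 0.95
        assert all(0.0 <= v <= 1.0 for v in tree.supports.values())

    def test_same_seed_reproduces_supports(self, separated):
        g, truth = separated
        t1 = phylo_time.bootstrap_supports(g, truth.cluster_labels, "DS", 50, 9, SSR)
        t2 = phylo_time.bootstrap_supports(g, truth.cluster_labels, "DS", 50, 9, SSR)
        assert t1.supports == t2.supports

    def test_supports_invariant_under_locus_reordering(self, separated):
        g, truth = separated
        shuffled = g.subset(locus_indices=list(reversed(range(g.n_loci))))
        t1 = phylo_time.bootstrap_supports(g, truth.cluster_labels, "DS", 100, 4, SSR)
        t2 = phylo_time.bootstrap_supports(shuffled, truth.cluster_labels, "DS", 100, 4, SSR)
        assert set(t1.supports) == set(t2.supports)

    def test_single_locus_bootstrap_degenerates_with_warning(self, separated):
        g, truth = separated
        single = g.subset(locus_indices=[0])
        with pytest.warns(UserWarning, match="single locus"):
            tree = phylo_time.bootstrap_supports(single, truth.cluster_labels, "DS", 10, 0, SSR)
        assert all(v == 1.0 for v in tree.supports.values())

    def test_newick_contains_supports_and_leaves(self, separated):
        g, truth = separated
        tree = phylo_time.bootstrap_supports(g, truth.cluster_labels, "DS", 20, 2, SSR)
        nwk = tree.newick()
        assert nwk.endswith(";")
        for leaf in ("A", "B", "C", "D"):
            assert leaf in nwk


class TestDivergenceTime:
    def test_zero_distance_gives_zero_generations(self):
        est = divergence_time(0.0)
        assert est.generations == (0.0, 0.0)

    def test_published_deepest_pair_value(self, table3):
        value = table3["dmu2_ssr"].value("K2", "K6")
        est = divergence_time(value, pair=("K2", "K6"))
        assert est.generations[0] == pytest.approx(7050.0)
        assert est.generations[1] == pytest.approx(1.41e6)
        assert est.years[0] == pytest.approx(7.05e5)
        assert est.years[1] == pytest.approx(1.41e8)

    def test_scaling_linear_in_distance_and_inverse_in_mu(self):
        base = divergence_time(2.0, mu_low=1e-4, mu_high=1e-3)
        doubled = divergence_time(4.0, mu_low=1e-4, mu_high=1e-3)
        halved_mu = divergence_time(2.0, mu_low=5e-5, mu_high=5e-4)
        assert doubled.generations[0] == pytest.approx(2 * base.generations[0])
        assert halved_mu.generations[1] == pytest.approx(2 * base.generations[1])

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValidationError):
            divergence_time(1.0, mu_low=0.0)
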