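"""RF distance, neighbor joining, alignment distances and the benchmark."""

import warnings

import dendropy
import numpy as np
import pytest
from Bio.Align import substitution_matrices

from orthoqc.discordance import (AlignmentParams, BenchmarkConfig,
                                 DistanceMatrix, UnrootedTree,
                                 neighbor_joining, ortholog_star,
                                 pairwise_distance, rf_distance, run_benchmark,
                                 select_representatives)
from orthoqc.io import parse_newick
from orthoqc.model import DataError, OrthologPairs, Proteome, ProteinRecord
from orthoqc.simulate import SimulationConfig, simulate_dataset


def random_newick(rng, labels):
    labels = list(labels)
    rng.shuffle(labels)

    def build(ls):
        if len(ls) == 1:
            return f"{ls[0]}:{rng.uniform(0.1, 1.0):.4f}"
        k = int(rng.integers(1, len(ls)))
        return f"({build(ls[:k])},{build(ls[k:])}):{rng.uniform(0.1, 1.0):.4f}"

    return build(labels) + ";"


def to_unrooted(newick):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return UnrootedTree.from_species_tree(parse_newick(newick, is_string=True))


def path_distance_matrix(tree: UnrootedTree):
    """Additive matrix: path lengths between leaves along tree edges."""
    leaf_nodes = {tree.label[n]: n for n in tree.adj
                  if len(tree.adj[n]) <= 1 and n in tree.label}
    labels = sorted(leaf_nodes)
    mat = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        # BFS with accumulated branch lengths
        dist = {leaf_nodes[a]: 0.0}
        stack = [leaf_nodes[a]]
        while stack:
            u = stack.pop()
            for v in tree.adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + tree.edge_length[frozenset((u, v))]
                    stack.append(v)
        for j, b in enumerate(labels):
            mat[i, j] = dist[leaf_nodes[b]]
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(labels=labels, matrix=mat)


class TestRFDistance:
    def test_identical_trees_zero(self):
        rng = np.random.default_rng(0)
        nwk = random_newick(rng, [f"L{i}" for i in range(7)])
        t = to_unrooted(nwk)
        assert rf_distance(t, t) == (0, 0.0)

    def test_maximally_discordant_binary_trees_scale_to_one(self):
        t1 = to_unrooted("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        t2 = to_unrooted("((A:1,D:1):1,(B:1,(C:1,E:1):1):1);")
        raw, scaled = rf_distance(t1, t2)
        assert scaled == 1.0

    def test_fewer_than_four_shared_leaves_is_error(self):
        t1 = to_unrooted("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = to_unrooted("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(DataError):
            rf_distance(t1, t2)

    def test_matches_dendropy_on_random_pairs(self):
        rng = np.random.default_rng(3)
        taxa = dendropy.TaxonNamespace()
        for _ in range(100):
            labels = [f"L{i}" for i in range(int(rng.integers(4, 8)))]
            n1, n2 = random_newick(rng, labels), random_newick(rng, labels)
            raw, _ = rf_distance(to_unrooted(n1), to_unrooted(n2))
            d1 = dendropy.Tree.get(data=n1, schema="newick",
                                   taxon_namespace=taxa)
            d2 = dendropy.Tree.get(data=n2, schema="newick",
                                   taxon_namespace=taxa)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert raw == expected

    def test_symmetry_and_identity_on_random_triples(self):
        rng = np.random.default_rng(4)
        labels = [f"L{i}" for i in range(6)]
        trees = [to_unrooted(random_newick(rng, labels)) for _ in range(3)]
        for a in trees:
            for b in trees:
                rab = rf_distance(a, b)
                rba = rf_distance(b, a)
                assert rab == rba
        # triangle inequality on the raw counts
        d = lambda x, y: rf_distance(x, y)[0]
        assert d(trees[0], trees[2]) <= d(trees[0], trees[1]) + d(trees[1], trees[2])


class TestNeighborJoining:
    def test_three_taxa_star(self):
        dm = DistanceMatrix(labels=["a", "b", "c"],
                            matrix=np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0.0]]))
        tree = neighbor_joining(dm)
        assert tree.leaves == {"a", "b", "c"}
        assert tree.splits() == set()

    def test_exact_recovery_from_additive_matrix(self):
        rng = np.random.default_rng(5)
        for n in (4, 6, 8, 12):
            labels = [f"T{i}" for i in range(n)]
            true = to_unrooted(random_newick(rng, labels))
            dm = path_distance_matrix(true)
            est = neighbor_joining(dm)
            assert est.splits() == true.splits()

    def test_label_permutation_leaves_splits_unchanged(self):
        rng = np.random.default_rng(6)
        labels = [f"T{i}" for i in range(8)]
        true = to_unrooted(random_newick(rng, labels))
        dm = path_distance_matrix(true)
        perm = rng.permutation(len(labels))
        dm2 = DistanceMatrix(labels=[dm.labels[i] for i in perm],
                             matrix=dm.matrix[np.ix_(perm, perm)])
        assert neighbor_joining(dm).splits() == neighbor_joining(dm2).splits()

    def test_invalid_matrix_rejected(self):
        with pytest.raises(DataError):
            DistanceMatrix(labels=["a", "b"], matrix=np.array([[0, 1], [2, 0.0]]))
        with pytest.raises(DataError):
            DistanceMatrix(labels=["a", "b"], matrix=np.array([[0, -1], [-1, 0.0]]))


def gotoh_score(a, b, matrix, open_gap=-11.0, extend_gap=-1.0):
    """Affine-gap global alignment score by dynamic programming (oracle)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_gap + extend_gap * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = open_gap + extend_gap * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_gap, X[i - 1, j] + extend_gap)
            Y[i, j] = max(M[i, j - 1] + open_gap, Y[i, j - 1] + extend_gap)
    return max(M[n, m], X[n, m], Y[n, m])


class TestPairwiseDistance:
    def test_identical_sequences_zero(self):
        assert pairwise_distance("MKVLW", "MKVLW") == 0.0

    def test_hand_alignment_example(self):
        d = pairwise_distance("ACDEFGHIK", "ACDEFGHIR")
        assert d == pytest.approx(1 - 8 / 9, abs=1e-9)

    def test_alignment_score_matches_dp_oracle(self):
        from Bio import Align
        rng = np.random.default_rng(8)
        blosum = substitution_matrices.load("BLOSUM62")
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = blosum
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        aligner.mode = "global"
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            s1 = "".join(rng.choice(list(aa), size=int(rng.integers(5, 15))))
            s2 = "".join(rng.choice(list(aa), size=int(rng.integers(5, 15))))
            assert aligner.score(s1, s2) == pytest.approx(
                gotoh_score(s1, s2, blosum))

    def test_distance_bounded_in_unit_interval(self):
        rng = np.random.default_rng(9)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            s1 = "".join(rng.choice(list(aa), size=30))
            s2 = "".join(rng.choice(list(aa), size=40))
            assert 0.0 <= pairwise_distance(s1, s2) <= 1.0


class TestStarsAndRepresentatives:
    def make_pairs(self):
        pairs = OrthologPairs()
        for pid in ("b1", "c1", "c2"):
            pairs.add("a1", pid)
        species_of = {"a1": "A", "b1": "B", "c1": "C", "c2": "C", "d9": "D"}
        return pairs, species_of

    def test_star_groups_by_species_including_seed(self):
        pairs, species_of = self.make_pairs()
        star = ortholog_star("a1", pairs, species_of)
        assert star == {"A": ["a1"], "B": ["b1"], "C": ["c1", "c2"]}

    def test_singleton_seed_covers_own_species_only(self):
        pairs, species_of = self.make_pairs()
        assert ortholog_star("d9", pairs, species_of) == {"D": ["d9"]}

    def test_fixed_seed_is_reproducible(self):
        pairs, species_of = self.make_pairs()
        star = ortholog_star("a1", pairs, species_of)
        r1 = select_representatives(star, np.random.default_rng(1))
        r2 = select_representatives(star, np.random.default_rng(1))
        assert r1 == r2

    def test_candidates_chosen_uniformly(self):
        star = {"C": ["c1", "c2", "c3"]}
        counts = {c: 0 for c in star["C"]}
        for s in range(10_000):
            counts[select_representatives(star, np.random.default_rng(s))["C"]] += 1
        for c, n in counts.items():
            # 3-sigma band around uniform 1/3
            assert abs(n / 10_000 - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 10_000)


@pytest.fixture(scope="module")
def bench_dataset():
    cfg = SimulationConfig(n_families=25, duplication_rate=0.0, loss_rate=0.0,
                           substitution_rate=0.5, root_length_median=400,
                           root_length_sigma=0.2, seed=21)
    return simulate_dataset(cfg)


class TestBenchmark:
    def test_same_seed_bit_identical(self, bench_dataset):
        ds = bench_dataset
        cfg = BenchmarkConfig(n_trials=12, min_species=10, seed=3)
        r1 = run_benchmark(ds.proteomes, ds.true_pairs, ds.config.tree(), cfg)
        r2 = run_benchmark(ds.proteomes, ds.true_pairs, ds.config.tree(), cfg)
        assert r1.recall == r2.recall
        assert [t.__dict__ for t in r1.trials] == [t.__dict__ for t in r2.trials]

    def test_raising_min_species_never_increases_recall(self, bench_dataset):
        ds = bench_dataset
        recalls = []
        for ms in (5, 10, 15, 20):
            cfg = BenchmarkConfig(n_trials=15, min_species=ms, seed=3)
            recalls.append(run_benchmark(ds.proteomes, ds.true_pairs,
                                         ds.config.tree(), cfg).recall)
        assert recalls == sorted(recalls, reverse=True)

    def test_singleton_only_dataset_recall_zero(self, bench_dataset):
        ds = bench_dataset
        cfg = BenchmarkConfig(n_trials=5, min_species=10, seed=1)
        res = run_benchmark(ds.proteomes, OrthologPairs(), ds.config.tree(), cfg)
        assert res.recall == 0
        assert res.mean_scaled_rf is None

    def test_clean_one_to_one_dataset_recalls_everything(self, bench_dataset):
        ds = bench_dataset
        cfg = BenchmarkConfig(n_trials=15, min_species=10, seed=5)
        res = run_benchmark(ds.proteomes, ds.true_pairs, ds.config.tree(), cfg)
        assert res.recall == res.n_trials
        assert res.mean_scaled_rf < 0.15
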