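"""Canonical isoform selection, ortholog proportions and HOG metrics."""

import pytest

from orthoqc.model import (DataError, HOG, HOGCollection, OrthologPairs,
                           Proteome, ProteinRecord, SpliceMap)
from orthoqc.orthology import (PhyleticPattern, count_pattern,
                               hog_completeness, hog_sizes, hogs_from_pairs,
                               ortholog_proportion, select_canonical_longest)


def proteome_of(species, entries):
    """entries: (protein id, gene id, length) triples."""
    return Proteome(label="t", species=species, proteins=[
        ProteinRecord(id=pid, gene_id=gid, species=species, sequence="A" * n)
        for pid, gid, n in entries])


class TestCanonicalSelection:
    def test_longest_isoform_wins(self):
        prot = proteome_of("sp", [("p1", "g1", 100), ("p2", "g1", 250)])
        out = select_canonical_longest(prot, SpliceMap({"g1": ["p1", "p2"]}))
        assert [p.id for p in out.canonical()] == ["p2"]

    def test_tie_broken_by_smallest_id(self):
        prot = proteome_of("sp", [("g1b", "g1", 100), ("g1a", "g1", 100)])
        out = select_canonical_longest(prot, SpliceMap({"g1": ["g1a", "g1b"]}))
        assert [p.id for p in out.canonical()] == ["g1a"]

    def test_without_splice_map_single_proteins_canonical(self):
        prot = proteome_of("sp", [("p1", "g1", 80), ("p2", "g2", 90)])
        out = select_canonical_longest(prot)
        assert sorted(p.id for p in out.canonical()) == ["p1", "p2"]

    def test_splice_filter_leaving_no_isoform_is_error(self):
        prot = proteome_of("sp", [("p1", "g1", 80), ("px", "g2", 10)])
        smap = SpliceMap({"g1": ["px"]})
        with pytest.raises(DataError):
            select_canonical_longest(prot, smap)


class TestOrthologProportion:
    def test_four_of_five_in_pairs(self):
        prot = select_canonical_longest(
            proteome_of("sp", [(f"p{i}", f"g{i}", 100) for i in range(5)]))
        pairs = OrthologPairs()
        for i in range(4):
            pairs.add(f"p{i}", f"x{i}")
        op = ortholog_proportion(prot, pairs)
        assert op.proportion == pytest.approx(0.8)
        assert op.singletons == {"p4"}

    def test_empty_pairs_all_singletons(self):
        prot = select_canonical_longest(
            proteome_of("sp", [("p1", "g1", 50), ("p2", "g2", 60)]))
        op = ortholog_proportion(prot, OrthologPairs())
        assert op.proportion == 0.0 and len(op.singletons) == 2

    def test_multi_isoform_denominator_counts_canonicals_only(self):
        entries = []
        for i in range(10):
            entries += [(f"g{i}a", f"g{i}", 100 + i), (f"g{i}b", f"g{i}", 50)]
        prot = select_canonical_longest(proteome_of("sp", entries))
        pairs = OrthologPairs()
        for i in range(7):
            pairs.add(f"g{i}a", f"y{i}")
        op = ortholog_proportion(prot, pairs)
        assert op.n_canonical == 10
        assert op.proportion == pytest.approx(0.7)

    def test_pair_touching_non_canonical_isoform_is_error(self):
        prot = select_canonical_longest(
            proteome_of("sp", [("g1a", "g1", 100), ("g1b", "g1", 50)]))
        pairs = OrthologPairs()
        pairs.add("g1b", "z1")
        with pytest.raises(DataError, match="not canonical"):
            ortholog_proportion(prot, pairs)

    def test_invariant_to_duplicate_pair_records(self):
        prot = select_canonical_longest(
            proteome_of("sp", [("p1", "g1", 50), ("p2", "g2", 60)]))
        pairs = OrthologPairs()
        pairs.add("p1", "q1")
        pairs.add("q1", "p1")
        pairs.add("p1", "q2")
        assert ortholog_proportion(prot, pairs).n_with_ortholog == 1


def hog(hid, level, members, children=()):
    return HOG(id=hid, level=level, members=tuple(members), children=tuple(children))


class TestHOGMetrics:
    def test_size_distribution(self):
        hogs = HOGCollection(profiles={
            "H1": {"a": 1, "b": 1}, "H2": {"a": 2}, "H3": {"a": 10, "b": 10}},
            species=["a", "b"])
        m = hog_sizes(hogs)
        assert m.n_roothogs == 3
        assert dict(m.size_distribution) == {2: 2, 20: 1}

    def test_empty_collection(self):
        m = hog_sizes(HOGCollection())
        assert m.n_roothogs == 0 and not m.size_distribution

    def test_nested_members_counted_once(self):
        child1 = hog("c1", "AB", [("A", "a1"), ("A", "a2"), ("B", "b1")])
        child2 = hog("c2", "AB", [("A", "a3"), ("B", "b2"), ("B", "b3")])
        root = hog("H1", "Root", child1.members + child2.members,
                   children=[child1, child2])
        coll = HOGCollection(roothogs=[root])
        m = hog_sizes(coll)
        assert m.n_roothogs == 1
        assert dict(m.size_distribution) == {6: 1}

    def test_completeness_against_clade(self, toy_tree):
        h = hog("H1", "AB", [("A", "a1")])
        assert hog_completeness(h, toy_tree) == pytest.approx(0.5)
        h2 = hog("H2", "Root", [("A", "a1"), ("B", "b1"), ("C", "c1")])
        assert hog_completeness(h2, toy_tree) == 1.0

    def test_unknown_level_is_error(self, toy_tree):
        with pytest.raises(DataError):
            hog_completeness(hog("H", "nope", [("A", "a1")]), toy_tree)


class TestPatternCounts:
    coll = HOGCollection(profiles={
        "H1": {"A": 1, "B": 1, "C": 1},
        "H2": {"A": 1, "B": 1, "C": 1},
        "H3": {"A": 2, "B": 1},
        "H4": {"A": 2, "B": 1},
        "H5": {"B": 1, "C": 1},
    }, species=["A", "B", "C"])

    def test_strict_single_copy_pattern(self):
        pat = PhyleticPattern.make({}, default=1)
        assert count_pattern(self.coll, pat) == 2

    def test_duplicated_and_absent_pattern(self):
        pat = PhyleticPattern.make({"A": 2, "C": 0}, default=1)
        assert count_pattern(self.coll, pat) == 2

    def test_all_wildcards_counts_everything(self):
        pat = PhyleticPattern.make({}, default="*")
        assert count_pattern(self.coll, pat) == len(self.coll)

    def test_unknown_species_is_error(self):
        with pytest.raises(DataError):
            count_pattern(self.coll, PhyleticPattern.make({"Z": 1}))

    def test_exhaustive_partition_sums_to_total(self):
        # partition on A's copy number: 0, 1, 2, >=3 (via wildcard difference)
        total = sum(count_pattern(self.coll,
                                  PhyleticPattern.make({"A": k}, default="*"))
                    for k in range(3))
        assert total == len(self.coll)


class TestHogsFromPairs:
    def test_components_with_level_from_lca(self, toy_tree):
        pairs = OrthologPairs()
        pairs.add("a1", "b1")
        pairs.add("b1", "c1")
        pairs.add("a9", "b9")
        species_of = {"a1": "A", "b1": "B", "c1": "C", "a9": "A", "b9": "B"}
        hogs = hogs_from_pairs(pairs, species_of, toy_tree)
        levels = sorted((h.size, h.level) for h in hogs.roothogs)
        assert levels == [(2, "AB"), (3, "Root")]
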