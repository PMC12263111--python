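"""Simulator ground truth, perturbation statistics and observed orthology."""

import numpy as np
import pytest

from orthoqc.agreement import gene_agreement
from orthoqc.model import OrthologPairs
from orthoqc.orthology import PhyleticPattern, count_pattern, ortholog_proportion
from orthoqc.simulate import (FamilyNode, PerturbationConfig, SimulatedTruth,
                              SimulationConfig, demo_species_tree,
                              evolve_sequences, observed_orthology,
                              perturb_annotation, simulate_dataset,
                              simulate_families, true_orthology)


class TestFamilySimulation:
    def test_zero_rates_give_strict_one_to_one(self, clean_dataset):
        tree = clean_dataset.config.tree()
        n_sp = len(tree.leaf_labels)
        for fam in clean_dataset.truth.families:
            species = [l.species_label for l in fam.root.leaves()]
            assert len(species) == n_sp
            assert len(set(species)) == n_sp

    def test_losses_remove_species(self):
        cfg = SimulationConfig(n_families=30, duplication_rate=0.0,
                               loss_rate=1.2, seed=9)
        truth = simulate_families(cfg)
        n_sp = len(cfg.tree().leaf_labels)
        sizes = [len(f.root.leaves()) for f in truth.families]
        assert max(sizes) < n_sp          # heavy loss prunes every family
        assert all(s >= 1 for s in sizes)  # extinct families are regenerated

    def test_wgd_with_full_retention_doubles_clade(self):
        cfg = SimulationConfig(n_families=15, duplication_rate=0.0,
                               loss_rate=0.0, seed=4,
                               wgd_events=(("Teleostei", 1.0),))
        truth = simulate_families(cfg)
        tree = cfg.tree()
        tele = tree.clade("Teleostei")
        _, hogs = true_orthology(truth)
        pat = PhyleticPattern.make({sp: 2 for sp in tele}, default=1)
        assert count_pattern(hogs, pat) == cfg.n_families

    def test_determinism_per_family_substream(self):
        cfg = SimulationConfig(n_families=5, seed=13)
        t1 = simulate_families(cfg)
        t2 = simulate_families(SimulationConfig(n_families=8, seed=13))
        # adding families never changes the first ones
        for f1, f2 in zip(t1.families, t2.families):
            assert [l.gene_id for l in f1.root.leaves()] == \
                   [l.gene_id for l in f2.root.leaves()]


class TestTrueOrthology:
    def test_one_to_one_family_pairs_and_root_hog(self, toy_tree):
        leafs = {sp: FamilyNode("leaf", sp, gene_id=f"{sp}_F0000_1")
                 for sp in "ABC"}
        root = FamilyNode("speciation", "Root", [
            FamilyNode("speciation", "AB", [leafs["A"], leafs["B"]]),
            leafs["C"]])
        cfg = SimulationConfig(species_tree=toy_tree, n_families=1)
        truth = SimulatedTruth(config=cfg, families=[
            __import__("orthoqc.simulate", fromlist=["Family"]).Family(0, root)],
            genes={l.gene_id: (0, sp) for sp, l in leafs.items()})
        pairs, hogs = true_orthology(truth)
        assert len(pairs) == 3
        assert len(hogs.roothogs) == 1
        assert hogs.roothogs[0].level == "Root"

    def test_duplication_before_split_separates_paralogs(self, toy_tree):
        # family tree: duplication above the (A,B) speciation
        def sp_node(tag):
            return FamilyNode("speciation", "AB", [
                FamilyNode("leaf", "A", gene_id=f"A_{tag}"),
                FamilyNode("leaf", "B", gene_id=f"B_{tag}")])
        root = FamilyNode("duplication", "AB", [sp_node("1"), sp_node("2")])
        cfg = SimulationConfig(species_tree=toy_tree, n_families=1)
        truth = SimulatedTruth(config=cfg, families=[
            __import__("orthoqc.simulate", fromlist=["Family"]).Family(0, root)],
            genes={g: (0, g[0]) for g in ("A_1", "B_1", "A_2", "B_2")})
        pairs, _ = true_orthology(truth)
        assert ("A_1", "B_1") in pairs and ("A_2", "B_2") in pairs
        assert ("A_1", "B_2") not in pairs and ("A_2", "B_1") not in pairs

    def test_all_pairs_cross_species(self, perturbed_dataset):
        species_of = perturbed_dataset.truth.species_of
        for a, b in perturbed_dataset.true_pairs:
            assert species_of[a] != species_of[b]


class TestSequencesAndModels:
    def test_zero_substitution_rate_identical_family_sequences(self):
        cfg = SimulationConfig(n_families=5, duplication_rate=0, loss_rate=0,
                               substitution_rate=0.0, seed=3)
        truth = simulate_families(cfg)
        proteomes, _ = evolve_sequences(truth)
        by_family = {}
        for sp, prot in proteomes.items():
            for p in prot:
                fam = truth.genes[p.id][0]
                by_family.setdefault(fam, set()).add(p.sequence)
        assert all(len(seqs) == 1 for seqs in by_family.values())

    def test_median_length_tracks_root_distribution(self):
        cfg = SimulationConfig(n_families=150, duplication_rate=0, loss_rate=0,
                               root_length_median=300, seed=6)
        truth = simulate_families(cfg)
        proteomes, _ = evolve_sequences(truth)
        for sp in ("Homo_sapiens", "Danio_rerio"):
            med = np.median([p.length for p in proteomes[sp]])
            assert abs(med - 300) / 300 < 0.10

    def test_emitted_gene_models_self_match(self, clean_dataset):
        ann = clean_dataset.annotations["Gallus_gallus"]
        assert gene_agreement(ann, ann).ji == 1.0


class TestPerturbation:
    def test_zero_perturbation_is_identity(self, clean_dataset):
        ds = clean_dataset
        for sp in ("Homo_sapiens", "Ciona_intestinalis"):
            assert all(f.status == "kept" for f in ds.ledgers[sp].fates.values())
            assert sorted(p.id for p in ds.perturbed_proteomes[sp]) == \
                   sorted(p.id for p in ds.proteomes[sp])
        assert ds.observed_pairs == ds.true_pairs

    def test_fraction_recovery_within_binomial_bounds(self):
        cfg = SimulationConfig(
            n_families=50, duplication_rate=0, loss_rate=0, seed=17,
            perturbation=PerturbationConfig(miss_prob=0.1, frag_prob=0.2,
                                            spurious_rate=0.3))
        ds = simulate_dataset(cfg)
        fates = [f for led in ds.ledgers.values()
                 for f in led.fates.values() if f.status != "spurious"]
        n = len(fates)
        assert n == 1000
        for status, p in (("missed", 0.1), ("fragmented", 0.2)):
            frac = sum(1 for f in fates if f.status == status) / n
            assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)
        n_spur = sum(len(led.spurious) for led in ds.ledgers.values())
        assert abs(n_spur / n - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / n)

    def test_fragment_spans_partition_protein(self, perturbed_dataset):
        for sp, led in perturbed_dataset.ledgers.items():
            for fate in led.fates.values():
                if fate.status != "fragmented":
                    continue
                spans = fate.fragment_spans
                assert spans[0][0] == 0 and spans[-1][1] == fate.length
                for (a, b), (c, d) in zip(spans, spans[1:]):
                    assert b == c and a < b and c < d
                for fid, (a, b) in zip(fate.fragments, spans):
                    assert perturbed_dataset.perturbed_proteomes[sp][fid].length \
                        == b - a

    def test_spurious_genes_shorten_the_proteome(self):
        cfg = SimulationConfig(
            n_families=40, duplication_rate=0, loss_rate=0, seed=23,
            perturbation=PerturbationConfig(spurious_rate=0.5,
                                            spurious_length_median=80))
        ds = simulate_dataset(cfg)
        sp = "Mus_musculus"
        before = np.median([p.length for p in ds.proteomes[sp]])
        after = np.median([p.length for p in ds.perturbed_proteomes[sp]])
        assert after < before


class TestObservedOrthology:
    def test_full_overlap_threshold_makes_fragments_singletons(self):
        cfg = SimulationConfig(
            n_families=20, duplication_rate=0, loss_rate=0, seed=31,
            overlap_threshold=1.0,
            perturbation=PerturbationConfig(frag_prob=0.5))
        ds = simulate_dataset(cfg)
        # no fragment may pair with a full-length partner at tau = 1
        frag_ids = {fid for led in ds.ledgers.values()
                    for f in led.fates.values() for fid in f.fragments}
        kept_ids = {f.gene_id for led in ds.ledgers.values()
                    for f in led.fates.values() if f.status == "kept"}
        for a, b in ds.observed_pairs:
            assert not ((a in frag_ids) ^ (b in frag_ids)), (a, b)
        assert kept_ids  # sanity: the check above is not vacuous

    def test_equal_fragments_fail_against_intact_partners(self):
        # tau = 0.6 with two fragments: at most one can reach 60% of the parent
        cfg = SimulationConfig(
            n_families=30, duplication_rate=0, loss_rate=0, seed=37,
            perturbation=PerturbationConfig(frag_prob=0.3))
        ds = simulate_dataset(cfg)
        tau = cfg.overlap_threshold
        for sp, led in ds.ledgers.items():
            for fate in led.fates.values():
                if fate.status != "fragmented":
                    continue
                for fid, (a, b) in zip(fate.fragments, fate.fragment_spans):
                    if (b - a) < tau * fate.length:
                        partners = ds.observed_pairs.partners(fid)
                        # any surviving partner must itself be a fragment
                        assert all("_f" in p for p in partners)

    def test_increasing_annotation_errors_decrease_proportion(self):
        # fragmentation and spurious genes rise together, as in a
        # degrading ab initio annotation
        props = []
        for level in (0.0, 0.2, 0.4):
            cfg = SimulationConfig(
                n_families=30, duplication_rate=0, loss_rate=0, seed=41,
                perturbation=PerturbationConfig(frag_prob=level,
                                                spurious_rate=level))
            ds = simulate_dataset(cfg)
            vals = [ortholog_proportion(pr, ds.observed_pairs).proportion
                    for pr in ds.perturbed_proteomes.values()]
            props.append(np.median(vals))
        assert props[0] > props[1] > props[2]
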