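"""Shared fixtures: toy trees, annotation builders, and small simulations."""

from __future__ import annotations

import numpy as np
import pytest

from orthoqc.io import parse_newick
from orthoqc.model import (AnnotationSet, GeneModel, GenomicInterval,
                           TranscriptModel)
from orthoqc.simulate import (PerturbationConfig, SimulationConfig,
                              simulate_dataset)


def make_transcript(tid, gene_id, exons, chrom="chr1", strand="+"):
    return TranscriptModel(
        id=tid, gene_id=gene_id,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons))


def make_annotation(label, species, gene_exons, chrom="chr1", strand="+"):
    """gene_exons: mapping gene id -> list of exon (start, end) pairs."""
    genes = []
    for gid, exons in gene_exons.items():
        tx = make_transcript(f"{gid}.t1", gid, exons, chrom=chrom, strand=strand)
        genes.append(GeneModel(id=gid, species=species, transcripts=[tx]))
    return AnnotationSet(label=label, species=species, genes=genes)


def random_annotation_pair(rng, n_genes=12, n_shared_chains=6):
    """Two annotations of one toy assembly sharing some intron chains.

    Used for brute-force equivalence checks of the agreement statistic.
    """
    def random_chain(start):
        n_exons = int(rng.integers(1, 5))
        exons = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(50, 300))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(80, 400))
        return exons

    chains = [random_chain(1000 + 5000 * i) for i in range(n_shared_chains)]

    def build(label):
        gene_exons = {}
        for g in range(int(rng.integers(1, n_genes + 1))):
            if rng.random() < 0.6 and chains:
                base = [list(e) for e in chains[int(rng.integers(len(chains)))]]
                # jitter terminal boundaries only: intron chain preserved
                base[0][0] = max(0, base[0][0] - int(rng.integers(0, 50)))
                base[-1][1] += int(rng.integers(0, 50))
                exons = [tuple(e) for e in base]
            else:
                exons = random_chain(int(rng.integers(0, 200_000)))
            gene_exons[f"{label}_g{g}"] = exons
        strand = "+" if rng.random() < 0.8 else "-"
        return make_annotation(label, "toy", gene_exons, strand=strand)

    return build("A"), build("B")


@pytest.fixture(scope="session")
def toy_tree():
    return parse_newick("((A:1,B:1)AB:1,C:2)Root;", is_string=True)


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-rate, zero-perturbation simulation on the demo 20-species tree."""
    cfg = SimulationConfig(n_families=25, duplication_rate=0.0, loss_rate=0.0,
                           seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def perturbed_dataset():
    """A small simulation with duplications, losses and annotation errors."""
    cfg = SimulationConfig(
        n_families=40, seed=11,
        perturbation=PerturbationConfig(miss_prob=0.1, frag_prob=0.2,
                                        spurious_rate=0.2, boundary_jitter=25))
    return simulate_dataset(cfg)
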