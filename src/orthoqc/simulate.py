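"""Gene-family and annotation simulator with known ground truth.

Families are born at the species-tree root and evolve along its branches
under a linear birth-death process (duplication/loss per unit branch
length), optionally punctuated by whole-genome duplications at named nodes
(every surviving copy duplicates; each new copy is retained with a stated
probability). Two extant genes are true orthologs iff their last common
ancestor in the family tree is a speciation node.

Sequences evolve by i.i.d. site substitution without indels, so protein
lengths are identical within a family and any length effect downstream is
attributable to the perturbation operators: missed genes, fragmentation
(a protein split into contiguous pieces at uniform cut points, with the
toy gene model split correspondingly), spurious genes with no family
membership, and terminal-exon boundary jitter.

The observed-orthology layer emulates an annotation-sensitive inference
with an OMA-style minimum alignment-overlap criterion: a pair between two
emitted units survives iff their parent genes are true orthologs and the
units' alignable region overlap covers at least ``overlap_threshold`` of
the longer unit. Full-length proteins of one family always pass; a
fragment fails against a full-length partner unless it retains most of the
protein, but fragments covering the same region of orthologous parents
still match -- reproducing both failure modes of fragmented annotations:
singletons, and separate shallow groups made of gene fragments.

Every stochastic step draws from an RNG substream named by
(seed, operation, family), so adding families or switching one stage never
reshuffles another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .model import (
    AnnotationSet,
    DataError,
    GeneModel,
    GenomicInterval,
    HOG,
    HOGCollection,
    OrthologPairs,
    Proteome,
    ProteinRecord,
    SpeciesTree,
    TranscriptModel,
    TreeNode,
)

__all__ = [
    "PerturbationConfig",
    "SimulationConfig",
    "FamilyNode",
    "Family",
    "SimulatedTruth",
    "GeneFate",
    "PerturbationLedger",
    "SimulatedDataset",
    "demo_species_tree",
    "simulate_families",
    "true_orthology",
    "evolve_sequences",
    "perturb_annotation",
    "observed_orthology",
    "simulate_dataset",
]

AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")

# RNG substream tags, one per stochastic operation
_OP_FAMILY, _OP_SEQUENCE, _OP_PERTURB = 1, 2, 3


# --------------------------------------------------------------------------
# Demo species tree: 20 chordate-like species, depth 1.0, labeled clades
# --------------------------------------------------------------------------

DEMO_TREE_NEWICK = (
    "(Ciona_intestinalis:1.0,"
    "((Erpetoichthys_calabaricus:0.7,(Lepisosteus_oculatus:0.65,"
    "(Danio_rerio:0.55,(Salmo_trutta:0.5,(Gadus_morhua:0.45,"
    "(Oryzias_latipes:0.4,(Echeneis_naucrates:0.3,Takifugu_rubripes:0.3)"
    "Carangaria:0.1)Percomorpha:0.05)Neoteleostei:0.05)Euteleostei:0.05)"
    "Teleostei:0.1)Neopterygii:0.05)Actinopterygii:0.15,"
    "(Xenopus_tropicalis:0.65,((Podarcis_erhardii:0.5,(Chrysemys_picta:0.45,"
    "(Gallus_gallus:0.25,(Strigops_habroptila:0.15,Taeniopygia_guttata:0.15)"
    "Neoaves:0.1)Aves:0.2)Archelosauria:0.05)Sauropsida:0.05,"
    "(Ornithorhynchus_anatinus:0.35,((Homo_sapiens:0.15,Mus_musculus:0.15)"
    "Euarchontoglires:0.15,(Felis_catus:0.15,Phocoena_sinus:0.15)"
    "Laurasiatheria:0.15)Theria:0.05)Mammalia:0.2)Amniota:0.1)"
    "Tetrapoda:0.2)Vertebrata:0.15)Chordata;"
)


def demo_species_tree() -> SpeciesTree:
    """The packaged 20-species demo tree (synthetic, chordate-like shape)."""
    from .io import parse_newick
    return parse_newick(DEMO_TREE_NEWICK, is_string=True)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationConfig:
    """Annotation error model, applied independently per gene."""

    miss_prob: float = 0.0          # gene removed entirely
    frag_prob: float = 0.0          # gene split into n_fragments pieces
    n_fragments: int = 2
    spurious_rate: float = 0.0      # spurious genes injected per true gene
    spurious_length_median: float = 120.0
    spurious_length_sigma: float = 0.5
    boundary_jitter: int = 0        # max shift (nt) of terminal exon ends

    def __post_init__(self) -> None:
        for name in ("miss_prob", "frag_prob", "spurious_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.miss_prob + self.frag_prob > 1.0:
            raise ValueError("miss_prob + frag_prob must be <= 1")
        if self.n_fragments < 2:
            raise ValueError("n_fragments must be >= 2")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Rates are per unit branch length of the species tree (the demo tree has
    root-to-tip depth 1). ``overlap_threshold`` is the minimum length ratio
    (shorter/longer) for an ortholog pair to be observed.
    """

    species_tree: Optional[SpeciesTree] = None   # None -> demo tree
    n_families: int = 300
    duplication_rate: float = 0.1
    loss_rate: float = 0.1
    wgd_events: Tuple[Tuple[str, float], ...] = ()
    root_length_median: float = 300.0
    root_length_sigma: float = 0.45
    substitution_rate: float = 0.3
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    overlap_threshold: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if not (0.0 < self.overlap_threshold <= 1.0):
            raise ValueError("overlap_threshold must be in (0, 1]")
        for node, retention in self.wgd_events:
            if not (0.0 <= retention <= 1.0):
                raise ValueError(f"WGD retention at {node!r} must be in [0, 1]")

    def tree(self) -> SpeciesTree:
        return self.species_tree if self.species_tree is not None else demo_species_tree()


# --------------------------------------------------------------------------
# Family trees
# --------------------------------------------------------------------------

@dataclass
class FamilyNode:
    """A node of a simulated gene-family tree.

    ``event`` is ``speciation``, ``duplication`` or ``leaf``; ``wgd`` marks
    duplications caused by a whole-genome duplication. ``t_parent`` is the
    evolutionary time separating the node from its parent.
    """

    event: str
    species_label: str
    children: List["FamilyNode"] = field(default_factory=list)
    gene_id: str = ""
    t_parent: float = 0.0
    wgd: bool = False

    def leaves(self) -> List["FamilyNode"]:
        if self.event == "leaf":
            return [self]
        out: List[FamilyNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Family:
    index: int
    root: FamilyNode
    n_losses: int = 0
    n_duplications: int = 0
    n_wgd_retained: int = 0


@dataclass
class SimulatedTruth:
    """Family forest plus the derived gene -> (family, species) map."""

    config: SimulationConfig
    families: List[Family]
    genes: Dict[str, Tuple[int, str]]   # gene id -> (family index, species)

    @property
    def species_of(self) -> Dict[str, str]:
        return {g: sp for g, (_, sp) in self.genes.items()}


def _simulate_branch(child: TreeNode, t_remaining: float, rng: np.random.Generator,
                     cfg: SimulationConfig, wgd_of: Mapping[str, float],
                     stats: Family) -> Optional[FamilyNode]:
    """One gene lineage travelling toward ``child``; returns the surviving
    subtree (t_parent measured from the segment start) or None if lost."""
    b, d = cfg.duplication_rate, cfg.loss_rate
    total = b + d
    wait = rng.exponential(1.0 / total) if total > 0 else math.inf
    if wait < t_remaining:
        if rng.random() < (b / total if total else 0.0):
            stats.n_duplications += 1
            left = _simulate_branch(child, t_remaining - wait, rng, cfg, wgd_of, stats)
            right = _simulate_branch(child, t_remaining - wait, rng, cfg, wgd_of, stats)
            if left is None and right is None:
                return None
            if left is None or right is None:
                survivor = left if left is not None else right
                survivor.t_parent += wait
                return survivor
            return FamilyNode("duplication", child.label, [left, right],
                              t_parent=wait)
        stats.n_losses += 1
        return None
    node = _arrive(child, rng, cfg, wgd_of, stats)
    if node is not None:
        node.t_parent += t_remaining
    return node


def _arrive(snode: TreeNode, rng: np.random.Generator, cfg: SimulationConfig,
            wgd_of: Mapping[str, float], stats: Family) -> Optional[FamilyNode]:
    """Lineage reaches the end of the branch leading to ``snode``.

    A WGD registered at ``snode`` fires here: the copy duplicates, the new
    copy retained with the configured probability."""
    if snode.label in wgd_of:
        retention = wgd_of[snode.label]
        first = _at_node(snode, rng, cfg, wgd_of, stats)
        keep_second = rng.random() < retention
        second = _at_node(snode, rng, cfg, wgd_of, stats) if keep_second else None
        if second is not None:
            stats.n_wgd_retained += 1
        if first is None and second is None:
            return None
        if first is None or second is None:
            return first if first is not None else second
        return FamilyNode("duplication", snode.label, [first, second], wgd=True)
    return _at_node(snode, rng, cfg, wgd_of, stats)


def _at_node(snode: TreeNode, rng: np.random.Generator, cfg: SimulationConfig,
             wgd_of: Mapping[str, float], stats: Family) -> Optional[FamilyNode]:
    if snode.is_leaf:
        return FamilyNode("leaf", snode.label)
    kids = []
    for c in snode.children:
        sub = _simulate_branch(c, c.length, rng, cfg, wgd_of, stats)
        if sub is not None:
            kids.append(sub)
    if not kids:
        return None
    if len(kids) == 1:
        # unary speciation nodes carry no orthology information; suppress
        return kids[0]
    return FamilyNode("speciation", snode.label, kids)


def simulate_families(config: SimulationConfig, max_retries: int = 50
                      ) -> SimulatedTruth:
    """Evolve ``n_families`` gene families along the species tree.

    All-extinct families are regenerated from a fresh substream (bounded
    retries). Gene ids are ``{species}_F{family:04d}_{copy}``.
    """
    tree = config.tree()
    wgd_of = dict(config.wgd_events)
    for label in wgd_of:
        tree.node(label)   # raises DataError on unknown labels
    families: List[Family] = []
    genes: Dict[str, Tuple[int, str]] = {}
    for fam_idx in range(config.n_families):
        fam = None
        for retry in range(max_retries):
            rng = np.random.default_rng([config.seed, _OP_FAMILY, fam_idx, retry])
            stats = Family(index=fam_idx, root=None)  # type: ignore[arg-type]
            root = _at_node(tree.root, rng, config, wgd_of, stats)
            if root is not None:
                stats.root = root
                fam = stats
                break
        if fam is None:
            raise DataError(f"family {fam_idx}: extinct in {max_retries} attempts; "
                            f"loss rate too high for this tree")
        counters: Dict[str, int] = {}
        for leaf in fam.root.leaves():
            sp = leaf.species_label
            counters[sp] = counters.get(sp, 0) + 1
            leaf.gene_id = f"{sp}_F{fam_idx:04d}_{counters[sp]}"
            genes[leaf.gene_id] = (fam_idx, sp)
        families.append(fam)
    return SimulatedTruth(config=config, families=families, genes=genes)


# --------------------------------------------------------------------------
# Ground-truth orthology
# --------------------------------------------------------------------------

def true_orthology(truth: SimulatedTruth) -> Tuple[OrthologPairs, HOGCollection]:
    """Speciation-LCA ortholog pairs and nested HOGs from the family forest.

    A pair is orthologous iff the two genes' LCA in their family tree is a
    speciation node. Each family yields one rootHOG whose level is the root
    clade (where every family originates); speciation nodes below map to
    their clade labels, duplication nodes become paralogous subgroups.
    """
    tree = truth.config.tree()
    pairs = OrthologPairs(species_of=truth.species_of)

    def collect(node: FamilyNode) -> List[Tuple[str, str]]:
        """Return (species, gene) leaves; emit cross-child pairs at speciations."""
        if node.event == "leaf":
            return [(node.species_label, node.gene_id)]
        per_child = [collect(c) for c in node.children]
        if node.event == "speciation":
            for i in range(len(per_child)):
                for j in range(i + 1, len(per_child)):
                    for _, g1 in per_child[i]:
                        for _, g2 in per_child[j]:
                            pairs.add(g1, g2)
        return [x for sub in per_child for x in sub]

    counter = [0]

    def to_hog(node: FamilyNode, fam_idx: int, level: str) -> HOG:
        counter[0] += 1
        hid = f"HOG{fam_idx:05d}.{counter[0]}"
        own_level = node.species_label if node.event == "speciation" else level
        members = tuple((l.species_label, l.gene_id) for l in node.leaves())
        children = tuple(
            to_hog(c, fam_idx, own_level)
            for c in node.children
            if c.event != "leaf" and len(c.leaves()) >= 2
        )
        return HOG(id=hid, level=own_level, members=members, children=children,
                   paralog=(node.event == "duplication"))

    roothogs = []
    for fam in truth.families:
        counter[0] = 0
        collect(fam.root)
        # the rootHOG is defined where the family originated: the tree root
        root_level = tree.root.label
        inner = to_hog(fam.root, fam.index, root_level)
        if inner.paralog:
            # OrthoXML-style top groups are ortholog groups; wrap the
            # root duplication as a nested paralogous subgroup
            hog = HOG(id=f"HOG{fam.index:05d}", level=root_level,
                      members=inner.members, children=(inner,))
        else:
            hog = replace(inner, id=f"HOG{fam.index:05d}", level=root_level)
        roothogs.append(hog)
    collection = HOGCollection(roothogs=roothogs, species=tree.leaf_labels)
    return pairs, collection


# --------------------------------------------------------------------------
# Sequences and toy gene models
# --------------------------------------------------------------------------

def _lognormal_length(rng: np.random.Generator, median: float, sigma: float,
                      minimum: int = 30) -> int:
    return max(minimum, int(round(median * math.exp(sigma * rng.standard_normal()))))


def _mutate(seq: np.ndarray, t: float, rate: float, rng: np.random.Generator
            ) -> np.ndarray:
    """Jukes-Cantor-style site replacement: each site substituted with
    probability 1 - exp(-rate * t), the new residue uniform over the other 19."""
    if rate <= 0 or t <= 0:
        return seq.copy()
    p = 1.0 - math.exp(-rate * t)
    out = seq.copy()
    mask = rng.random(seq.size) < p
    if mask.any():
        idx = np.flatnonzero(mask)
        cur = np.searchsorted(AA, out[idx])
        shift = rng.integers(1, 20, size=idx.size)
        out[idx] = AA[(cur + shift) % 20]
    return out


def _exon_layout(n_aa: int) -> List[int]:
    """Deterministic exon nt lengths for a protein of ``n_aa`` residues:
    one exon per started 200 codons, sizes as equal as integer division allows."""
    cds = 3 * n_aa
    n_exons = max(1, (n_aa + 199) // 200)
    base, extra = divmod(cds, n_exons)
    return [base + (1 if i < extra else 0) for i in range(n_exons)]


_INTRON = 200
_SPACER = 1000


def evolve_sequences(truth: SimulatedTruth
                     ) -> Tuple[Dict[str, Proteome], Dict[str, AnnotationSet]]:
    """Evolve protein sequences down each family tree and synthesize toy
    gene models (protein id == gene id; one transcript per gene)."""
    cfg = truth.config
    tree = cfg.tree()
    species = tree.leaf_labels
    seqs: Dict[str, str] = {}
    for fam in truth.families:
        rng = np.random.default_rng([cfg.seed, _OP_SEQUENCE, fam.index])
        length = _lognormal_length(rng, cfg.root_length_median, cfg.root_length_sigma)
        root_seq = AA[rng.integers(0, 20, size=length)]

        def walk(node: FamilyNode, seq: np.ndarray) -> None:
            seq = _mutate(seq, node.t_parent, cfg.substitution_rate, rng)
            if node.event == "leaf":
                seqs[node.gene_id] = seq.tobytes().decode("ascii")
                return
            for c in node.children:
                walk(c, seq)

        walk(fam.root, root_seq)

    proteomes: Dict[str, Proteome] = {}
    annotations: Dict[str, AnnotationSet] = {}
    for sp in species:
        gids = sorted(g for g, (_, s) in truth.genes.items() if s == sp)
        proteome = Proteome(label="truth", species=sp)
        genes: List[GeneModel] = []
        offset = _SPACER
        for i, gid in enumerate(gids):
            seq = seqs[gid]
            proteome.add(ProteinRecord(id=gid, gene_id=gid, species=sp,
                                       sequence=seq, canonical=True))
            strand = "+" if i % 2 == 0 else "-"
            exons = []
            pos = offset
            for exon_nt in _exon_layout(len(seq)):
                exons.append(GenomicInterval("chr1", pos, pos + exon_nt, strand))
                pos += exon_nt + _INTRON
            tx = TranscriptModel(id=f"{gid}.t1", gene_id=gid, exons=tuple(exons))
            genes.append(GeneModel(id=gid, species=sp, transcripts=[tx]))
            offset = exons[-1].end + _SPACER
        proteomes[sp] = proteome
        annotations[sp] = AnnotationSet(label="truth", species=sp, genes=genes)
    return proteomes, annotations


# --------------------------------------------------------------------------
# Annotation perturbation
# --------------------------------------------------------------------------

@dataclass
class GeneFate:
    gene_id: str
    status: str                     # kept | missed | fragmented | spurious
    length: int = 0                 # original protein length (residues)
    fragments: Tuple[str, ...] = ()
    fragment_spans: Tuple[Tuple[int, int], ...] = ()  # residue intervals [a, b)
    parent: Optional[str] = None    # for fragments/spurious: source gene or None


@dataclass
class PerturbationLedger:
    """Per-gene record of what the perturbation did, plus spurious ids."""

    species: str
    fates: Dict[str, GeneFate] = field(default_factory=dict)
    spurious: List[str] = field(default_factory=list)

    def units_of(self, gene_id: str) -> Tuple[str, ...]:
        """Emitted annotation units descending from a true gene."""
        fate = self.fates[gene_id]
        if fate.status == "kept":
            return (gene_id,)
        if fate.status == "fragmented":
            return fate.fragments
        return ()

    def spans_of(self, gene_id: str) -> Tuple[Tuple[int, int], ...]:
        """Residue intervals of the emitted units, in the coordinates of the
        original protein (a kept gene spans [0, length))."""
        fate = self.fates[gene_id]
        if fate.status == "kept":
            return ((0, fate.length),)
        if fate.status == "fragmented":
            return fate.fragment_spans
        return ()

    def fraction(self, status: str) -> float:
        true_genes = [f for f in self.fates.values() if f.status != "spurious"]
        if not true_genes:
            return 0.0
        return sum(1 for f in true_genes if f.status == status) / len(true_genes)


def _split_transcript(tx: TranscriptModel, nt_cuts: Sequence[int],
                      fragment_ids: Sequence[str]) -> List[TranscriptModel]:
    """Split a transcript's exon chain at CDS-relative nt offsets."""
    bounds = [0] + list(nt_cuts) + [sum(len(e) for e in tx.exons)]
    out = []
    for fi, (a, b) in enumerate(zip(bounds, bounds[1:])):
        pieces = []
        acc = 0
        for e in tx.exons:
            lo, hi = acc, acc + len(e)
            s, t = max(a, lo), min(b, hi)
            if s < t:
                pieces.append(GenomicInterval(e.chrom, e.start + (s - lo),
                                              e.start + (t - lo), e.strand))
            acc = hi
        out.append(TranscriptModel(id=f"{fragment_ids[fi]}.t1",
                                   gene_id=fragment_ids[fi], exons=tuple(pieces)))
    return out


def perturb_annotation(proteome: Proteome, annotation: AnnotationSet,
                       truth: SimulatedTruth,
                       config: Optional[SimulationConfig] = None
                       ) -> Tuple[Proteome, AnnotationSet, PerturbationLedger]:
    """Apply the annotation error model to one species.

    Independently per gene: missed with ``miss_prob``; fragmented with
    ``frag_prob`` (protein cut at ``n_fragments - 1`` distinct uniform
    interior residues, the gene model split at the corresponding CDS
    offsets); otherwise kept. Spurious genes are injected per true gene at
    ``spurious_rate`` with lognormal lengths and no family membership.
    Terminal-exon boundary jitter shifts the outer ends of surviving gene
    models by up to ``boundary_jitter`` nt.
    """
    cfg = config or truth.config
    p = cfg.perturbation
    sp = proteome.species
    ledger = PerturbationLedger(species=sp)
    out_prot = Proteome(label=f"{proteome.label}+perturbed", species=sp)
    out_genes: List[GeneModel] = []
    sp_index = sorted(truth.config.tree().leaf_labels).index(sp)
    rng_of_fam: Dict[int, np.random.Generator] = {}

    def fam_rng(gid: str) -> np.random.Generator:
        # one substream per (family, species): adding families or species
        # never reshuffles the fates of existing ones
        fam_idx = truth.genes[gid][0]
        if fam_idx not in rng_of_fam:
            rng_of_fam[fam_idx] = np.random.default_rng(
                [cfg.seed, _OP_PERTURB, fam_idx, sp_index])
        return rng_of_fam[fam_idx]

    def jitter(tx: TranscriptModel, rng: np.random.Generator) -> TranscriptModel:
        if p.boundary_jitter <= 0:
            return tx
        exons = list(tx.exons)
        first, last = exons[0], exons[-1]
        j = int(p.boundary_jitter)
        d1 = int(rng.integers(-j, j + 1))
        d2 = int(rng.integers(-j, j + 1))
        new_start = max(0, min(first.start + d1, first.end - 1))
        exons[0] = GenomicInterval(first.chrom, new_start, first.end, first.strand)
        last = exons[-1]
        new_end = max(last.start + 1, last.end + d2)
        if len(exons) > 1 and new_end <= exons[-2].end:
            new_end = last.end
        exons[-1] = GenomicInterval(last.chrom, last.start, new_end, last.strand)
        return TranscriptModel(id=tx.id, gene_id=tx.gene_id, exons=tuple(exons))

    spur_count = 0
    spur_offset = None
    for gene in sorted(annotation, key=lambda g: g.id):
        gid = gene.id
        prot = proteome[gid]
        rng = fam_rng(gid)
        u = rng.random()
        if u < p.miss_prob:
            ledger.fates[gid] = GeneFate(gid, "missed", length=prot.length)
        elif u < p.miss_prob + p.frag_prob:
            L = prot.length
            n_frag = min(p.n_fragments, L)
            cuts = sorted(int(c) for c in
                          rng.choice(np.arange(1, L), size=n_frag - 1, replace=False))
            frag_ids = tuple(f"{gid}_f{i + 1}" for i in range(n_frag))
            bounds = [0] + cuts + [L]
            for fi, (a, b) in enumerate(zip(bounds, bounds[1:])):
                out_prot.add(ProteinRecord(id=frag_ids[fi], gene_id=frag_ids[fi],
                                           species=sp, sequence=prot.sequence[a:b],
                                           canonical=True))
            tx = gene.transcripts[0]
            frag_txs = _split_transcript(tx, [3 * c for c in cuts], frag_ids)
            for fi, ftx in enumerate(frag_txs):
                out_genes.append(GeneModel(id=frag_ids[fi], species=sp,
                                           transcripts=[jitter(ftx, rng)]))
            ledger.fates[gid] = GeneFate(gid, "fragmented", length=L,
                                         fragments=frag_ids,
                                         fragment_spans=tuple(zip(bounds, bounds[1:])),
                                         parent=gid)
        else:
            out_prot.add(ProteinRecord(id=gid, gene_id=gid, species=sp,
                                       sequence=prot.sequence, canonical=True))
            out_genes.append(GeneModel(id=gid, species=sp,
                                       transcripts=[jitter(gene.transcripts[0], rng)]))
            ledger.fates[gid] = GeneFate(gid, "kept", length=prot.length)
        # spurious injection, tied to the same per-family stream
        if rng.random() < p.spurious_rate:
            spur_count += 1
            sid = f"{sp}_SPUR_{spur_count:04d}"
            length = _lognormal_length(rng, p.spurious_length_median,
                                       p.spurious_length_sigma)
            seq = AA[rng.integers(0, 20, size=length)].tobytes().decode("ascii")
            out_prot.add(ProteinRecord(id=sid, gene_id=sid, species=sp,
                                       sequence=seq, canonical=True))
            if spur_offset is None:
                spur_offset = max((t.span[1] for g in annotation
                                   for t in g.transcripts), default=0) + 10 * _SPACER
            exons = []
            pos = spur_offset
            for exon_nt in _exon_layout(length):
                exons.append(GenomicInterval("chr1", pos, pos + exon_nt, "+"))
                pos += exon_nt + _INTRON
            spur_offset = exons[-1].end + _SPACER
            out_genes.append(GeneModel(id=sid, species=sp, transcripts=[
                TranscriptModel(id=f"{sid}.t1", gene_id=sid, exons=tuple(exons))]))
            ledger.fates[sid] = GeneFate(sid, "spurious", length=length)
            ledger.spurious.append(sid)
    out_ann = AnnotationSet(label=f"{annotation.label}+perturbed", species=sp,
                            genes=out_genes)
    return out_prot, out_ann, ledger


# --------------------------------------------------------------------------
# Observed orthology
# --------------------------------------------------------------------------

def observed_orthology(perturbed: Mapping[str, Proteome], truth: SimulatedTruth,
                       ledgers: Mapping[str, PerturbationLedger],
                       true_pairs: Optional[OrthologPairs] = None
                       ) -> OrthologPairs:
    """Emulate annotation-sensitive ortholog inference on perturbed proteomes.

    A pair between two emitted units is observed iff their source genes are
    true orthologs and the units' alignable overlap -- the intersection of
    their residue spans in the (indel-free) family coordinate system -- is
    at least ``overlap_threshold`` times the longer unit. For a fragment
    against a full-length partner this is exactly the rule that a fragment
    keeps its parent's pairs only when it covers at least that fraction of
    the protein; two fragments covering the same region still match each
    other, while non-overlapping fragments never do. Spurious and missed
    genes contribute nothing.
    """
    cfg = truth.config
    tau = cfg.overlap_threshold
    if true_pairs is None:
        true_pairs, _ = true_orthology(truth)
    species_of: Dict[str, str] = {}
    for sp, proteome in perturbed.items():
        for p in proteome:
            species_of[p.id] = sp
    observed = OrthologPairs(species_of=species_of)
    for g1, g2 in true_pairs:
        led1 = ledgers[truth.genes[g1][1]]
        led2 = ledgers[truth.genes[g2][1]]
        for u1, (a1, b1) in zip(led1.units_of(g1), led1.spans_of(g1)):
            for u2, (a2, b2) in zip(led2.units_of(g2), led2.spans_of(g2)):
                overlap = min(b1, b2) - max(a1, a2)
                if overlap >= tau * max(b1 - a1, b2 - a2):
                    observed.add(u1, u2)
    return observed


# --------------------------------------------------------------------------
# One-call dataset bundle
# --------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Everything one simulation run produces."""

    config: SimulationConfig
    truth: SimulatedTruth
    true_pairs: OrthologPairs
    true_hogs: HOGCollection
    proteomes: Dict[str, Proteome]
    annotations: Dict[str, AnnotationSet]
    perturbed_proteomes: Dict[str, Proteome]
    perturbed_annotations: Dict[str, AnnotationSet]
    ledgers: Dict[str, PerturbationLedger]
    observed_pairs: OrthologPairs


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write a simulated dataset to disk in the standard formats.

    Two annotation sources are emitted: ``truth`` (the clean simulation with
    its true pairs and HOGs) and ``perturbed`` (the error-model outputs with
    the observed pairs and the flat groups they support), plus the species
    tree and the perturbation ledger.
    """
    from pathlib import Path

    from . import io as oio
    from .orthology import hogs_from_pairs

    out = Path(outdir)
    tree = ds.config.tree()
    oio.write_newick(tree, _ensure(out / "tree.nwk"))

    for label, proteomes, annotations, pairs in (
            ("truth", ds.proteomes, ds.annotations, ds.true_pairs),
            ("perturbed", ds.perturbed_proteomes, ds.perturbed_annotations,
             ds.observed_pairs)):
        d = out / label
        d.mkdir(parents=True, exist_ok=True)
        for sp in sorted(proteomes):
            oio.write_fasta(proteomes[sp], d / f"{sp}.fa")
            oio.write_gff3(annotations[sp], d / f"{sp}.gff3")
        oio.write_pairwise(pairs, d / "pairs.tsv")
    oio.write_orthoxml(ds.true_hogs, out / "truth" / "hogs.orthoxml")
    oio.write_profile_tsv(ds.true_hogs, out / "truth" / "profiles.tsv")
    species_of = {p.id: sp for sp, pr in ds.perturbed_proteomes.items() for p in pr}
    observed_hogs = hogs_from_pairs(ds.observed_pairs, species_of, tree)
    oio.write_orthoxml(observed_hogs, out / "perturbed" / "hogs.orthoxml")
    oio.write_profile_tsv(observed_hogs, out / "perturbed" / "profiles.tsv")

    with open(out / "ledger.tsv", "w") as fh:
        fh.write("species\tgene\tstatus\tlength\tunits\n")
        for sp in sorted(ds.ledgers):
            led = ds.ledgers[sp]
            for gid in sorted(led.fates):
                fate = led.fates[gid]
                units = ";".join(led.units_of(gid)) if fate.status != "spurious" \
                    else gid
                fh.write(f"{sp}\t{gid}\t{fate.status}\t{fate.length}\t{units}\n")


def _ensure(path):
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate families, sequences, gene models, perturbations and the
    observed ortholog pairs in one call."""
    truth = simulate_families(config)
    true_pairs, true_hogs = true_orthology(truth)
    proteomes, annotations = evolve_sequences(truth)
    perturbed_p: Dict[str, Proteome] = {}
    perturbed_a: Dict[str, AnnotationSet] = {}
    ledgers: Dict[str, PerturbationLedger] = {}
    for sp in sorted(proteomes):
        pp, pa, led = perturb_annotation(proteomes[sp], annotations[sp], truth, config)
        perturbed_p[sp] = pp
        perturbed_a[sp] = pa
        ledgers[sp] = led
    observed = observed_orthology(perturbed_p, truth, ledgers, true_pairs)
    return SimulatedDataset(config=config, truth=truth, true_pairs=true_pairs,
                            true_hogs=true_hogs, proteomes=proteomes,
                            annotations=annotations,
                            perturbed_proteomes=perturbed_p,
                            perturbed_annotations=perturbed_a,
                            ledgers=ledgers, observed_pairs=observed)
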