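"""Species-tree discordance benchmark.

Repeatedly samples a seed protein, collects one ortholog per covered
species, builds a gene tree (global-alignment p-distances + neighbor
joining), and scores it against the species tree with the scaled
Robinson-Foulds distance. Recall is the number of trials whose ortholog
set covers at least ``min_species`` species and yields a usable tree;
accuracy is the mean scaled RF over those successful trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .model import DataError, OrthologPairs, Proteome, SpeciesTree

__all__ = [
    "UnrootedTree",
    "DistanceMatrix",
    "AlignmentParams",
    "BenchmarkConfig",
    "TrialRecord",
    "BenchmarkResult",
    "ortholog_star",
    "select_representatives",
    "pairwise_distance",
    "neighbor_joining",
    "rf_distance",
    "run_benchmark",
]


# --------------------------------------------------------------------------
# Unrooted trees and Robinson-Foulds distance
# --------------------------------------------------------------------------

class UnrootedTree:
    """An unrooted leaf-labeled tree stored as an adjacency map.

    Node ids are integers; leaves carry labels. Branch lengths are kept per
    edge (unordered node pair) and may be absent.
    """

    def __init__(self) -> None:
        self.adj: Dict[int, Set[int]] = {}
        self.label: Dict[int, str] = {}
        self.edge_length: Dict[FrozenSet[int], float] = {}
        self._next = 0

    def new_node(self, label: Optional[str] = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        if label is not None:
            self.label[nid] = label
        return nid

    def connect(self, a: int, b: int, length: float = 0.0) -> None:
        self.adj[a].add(b)
        self.adj[b].add(a)
        self.edge_length[frozenset((a, b))] = length

    @property
    def leaves(self) -> FrozenSet[str]:
        return frozenset(self.label[n] for n in self.adj
                         if len(self.adj[n]) <= 1 and n in self.label)

    @classmethod
    def from_species_tree(cls, tree: SpeciesTree) -> "UnrootedTree":
        """Unroot a rooted tree (a degree-2 root is suppressed)."""
        t = cls()

        def build(node, parent_id: Optional[int]) -> int:
            nid = t.new_node(node.label if node.is_leaf else None)
            if parent_id is not None:
                t.connect(parent_id, nid, node.length)
            for c in node.children:
                build(c, nid)
            return nid

        root_id = build(tree.root, None)
        nbrs = list(t.adj[root_id])
        if len(nbrs) == 2 and root_id not in t.label:
            a, b = nbrs
            la = t.edge_length.pop(frozenset((root_id, a)))
            lb = t.edge_length.pop(frozenset((root_id, b)))
            t.adj[a].discard(root_id)
            t.adj[b].discard(root_id)
            del t.adj[root_id]
            t.connect(a, b, la + lb)
        return t

    def splits(self, restrict_to: Optional[Iterable[str]] = None
               ) -> Set[FrozenSet[str]]:
        """Non-trivial bipartitions as canonical leaf-label sets.

        With ``restrict_to``, splits are restricted to that leaf subset
        (equivalent to pruning the tree first) and deduplicated. Each split
        is represented by the side not containing the smallest leaf label.
        """
        leaf_set = self.leaves if restrict_to is None else frozenset(restrict_to) & self.leaves
        if not leaf_set:
            return set()
        anchor = min(leaf_set)
        out: Set[FrozenSet[str]] = set()
        seen_edges = set()
        for u in self.adj:
            for v in self.adj[u]:
                e = frozenset((u, v))
                if e in seen_edges:
                    continue
                seen_edges.add(e)
                side = frozenset(self._leaves_on_side(v, u)) & leaf_set
                if anchor in side:
                    side = leaf_set - side
                if 2 <= len(side) <= len(leaf_set) - 2:
                    out.add(side)
        return out

    def _leaves_on_side(self, start: int, blocked: int) -> List[str]:
        out = []
        stack = [start]
        seen = {blocked, start}
        while stack:
            n = stack.pop()
            if n in self.label and len(self.adj[n]) <= 1:
                out.append(self.label[n])
            for m in self.adj[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return out


def rf_distance(t1: UnrootedTree, t2: UnrootedTree) -> Tuple[int, float]:
    """Robinson-Foulds distance on the shared leaf set.

    Both trees are restricted to their shared leaves; ``raw`` counts
    bipartitions present in one tree but not the other, and the scaled
    value divides by the total number of bipartitions in the two restricted
    trees, so it lies in [0, 1] with 1 for maximally discordant binary
    trees. Multifurcating trees simply contribute fewer bipartitions.
    """
    shared = t1.leaves & t2.leaves
    if len(shared) < 4:
        raise DataError(f"RF distance needs >=4 shared leaves, got {len(shared)}")
    b1 = t1.splits(restrict_to=shared)
    b2 = t2.splits(restrict_to=shared)
    raw = len(b1 ^ b2)
    denom = len(b1) + len(b2)
    scaled = raw / denom if denom else 0.0
    return raw, scaled


# --------------------------------------------------------------------------
# Distance matrices and neighbor joining
# --------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise DataError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise DataError("distance matrix not symmetric")
        if (d < 0).any():
            raise DataError("negative distances")
        if not np.allclose(np.diag(d), 0):
            raise DataError("nonzero diagonal")
        if not np.isfinite(d).all():
            raise DataError("non-finite distances")
        self.matrix = d


def neighbor_joining(dm: DistanceMatrix) -> UnrootedTree:
    """Standard neighbor joining with deterministic tie-breaking.

    Q-matrix ties are broken by the smallest (representative-label) pair,
    where a cluster's representative is the smallest original label it
    contains. Negative branch lengths are clamped to zero. Consistent on
    additive matrices: recovers the generating topology exactly.
    """
    n = len(dm.labels)
    if n < 3:
        raise DataError("neighbor joining needs >=3 labels")
    if len(set(dm.labels)) != n:
        raise DataError("duplicate labels")

    tree = UnrootedTree()
    nodes = [tree.new_node(lab) for lab in dm.labels]
    reps = list(dm.labels)
    d = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * sub[i, j] - r[i] - r[j]
                ri, rj = reps[active[i]], reps[active[j]]
                key = (q, min(ri, rj), max(ri, rj))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        if m > 2:
            li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        else:
            li = 0.5 * dij
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        new = tree.new_node()
        tree.connect(new, nodes[ai], li)
        tree.connect(new, nodes[aj], lj)

        # distances from the new cluster to the remaining ones
        d = np.pad(d, ((0, 1), (0, 1)))
        k_new = d.shape[0] - 1
        for k in active:
            if k in (ai, aj):
                continue
            d[k_new, k] = d[k, k_new] = 0.5 * (d[ai, k] + d[aj, k] - dij)
        nodes.append(new)
        reps.append(min(reps[ai], reps[aj]))
        active = [k for k in active if k not in (ai, aj)] + [k_new]

    a, b = active
    tree.connect(nodes[a], nodes[b], max(d[a, b], 0.0))
    return tree


# --------------------------------------------------------------------------
# Alignment p-distance
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentParams:
    """Global protein alignment settings for gene-tree distances."""

    matrix: str = "BLOSUM62"
    open_gap: float = -11.0
    extend_gap: float = -1.0


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.open_gap
    aligner.extend_gap_score = params.extend_gap
    aligner.mode = "global"
    return aligner


def pairwise_distance(a: str, b: str,
                      params: AlignmentParams = AlignmentParams(),
                      _aligner: Optional[Align.PairwiseAligner] = None) -> float:
    """Global-alignment p-distance: 1 - identities / aligned columns.

    Columns where either sequence has a gap are excluded from both the
    numerator and the denominator.
    """
    if not a or not b:
        raise DataError("empty sequence")
    a = a.rstrip("*").upper()
    b = b.rstrip("*").upper()
    aligner = _aligner if _aligner is not None else _make_aligner(params)
    aln = aligner.align(a, b)[0]
    ident = 0
    columns = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        columns += e1 - s1
        for x, y in zip(a[s1:e1], b[s2:e2]):
            if x == y:
                ident += 1
    if columns == 0:
        warnings.warn("alignment has no aligned (non-gap) columns; distance = 1")
        return 1.0
    return 1.0 - ident / columns


# --------------------------------------------------------------------------
# Benchmark
# --------------------------------------------------------------------------

@dataclass
class BenchmarkConfig:
    n_trials: int = 50_000
    min_species: int = 10
    seed: int = 0
    alignment: AlignmentParams = AlignmentParams()

    def validate(self, n_species: int) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (2 < self.min_species <= n_species):
            raise ValueError(f"min_species must be in (2, {n_species}]")


@dataclass
class TrialRecord:
    index: int
    seed_protein: str
    n_species: int
    status: str                       # success | low_coverage | degenerate
    raw_rf: Optional[int] = None
    scaled_rf: Optional[float] = None


@dataclass
class BenchmarkResult:
    n_trials: int
    n_success: int
    mean_scaled_rf: Optional[float]
    trials: List[TrialRecord] = field(default_factory=list)

    @property
    def recall(self) -> int:
        return self.n_success


def ortholog_star(seed_protein: str, pairs: OrthologPairs,
                  species_of: Mapping[str, str]) -> Dict[str, List[str]]:
    """All proteins paired with the seed, grouped by species; the seed's own
    species maps to the seed itself."""
    if seed_protein not in species_of:
        raise DataError(f"unknown seed protein {seed_protein!r}")
    star: Dict[str, List[str]] = {species_of[seed_protein]: [seed_protein]}
    for p in sorted(pairs.partners(seed_protein)):
        star.setdefault(species_of[p], []).append(p)
    return star


def select_representatives(star: Mapping[str, Sequence[str]],
                           rng: np.random.Generator) -> Dict[str, str]:
    """One protein per covered species, chosen uniformly with the trial RNG."""
    if not star:
        raise ValueError("empty ortholog star")
    out = {}
    for sp in sorted(star):
        cands = sorted(star[sp])
        out[sp] = cands[int(rng.integers(len(cands)))]
    return out


def run_benchmark(proteomes: Mapping[str, Proteome], pairs: OrthologPairs,
                  species_tree: SpeciesTree,
                  config: BenchmarkConfig) -> BenchmarkResult:
    """Run the discordance benchmark.

    Per trial a seed protein is drawn uniformly from the union of canonical
    proteins (with replacement across trials). The trial succeeds iff the
    seed's ortholog star covers >= ``min_species`` species and the NJ gene
    tree is informative (a non-degenerate distance matrix with at least one
    non-trivial bipartition); on success the scaled RF distance against the
    species tree restricted to the covered species is recorded. Each trial
    draws from an RNG stream derived from (seed, trial index), so runs are
    bit-reproducible.
    """
    config.validate(len(species_tree.leaf_labels))

    sequences: Dict[str, str] = {}
    species_of: Dict[str, str] = {}
    for sp, proteome in proteomes.items():
        if sp not in species_tree:
            raise DataError(f"species {sp!r} not in species tree")
        for p in proteome.canonical():
            sequences[p.id] = p.sequence
            species_of[p.id] = proteome.species
    if not sequences:
        raise DataError("no canonical proteins; canonicalize proteomes first")
    pool = sorted(sequences)

    partner_idx = pairs.partner_index()
    aligner = _make_aligner(config.alignment)
    dist_cache: Dict[FrozenSet[str], float] = {}
    unrooted_species = UnrootedTree.from_species_tree(species_tree)

    trials: List[TrialRecord] = []
    n_success = 0
    rf_sum = 0.0

    for t in range(config.n_trials):
        rng = np.random.default_rng([config.seed, t])
        seed_id = pool[int(rng.integers(len(pool)))]
        star: Dict[str, List[str]] = {species_of[seed_id]: [seed_id]}
        for p in partner_idx.get(seed_id, ()):
            sp = species_of.get(p)
            if sp is not None:
                star.setdefault(sp, []).append(p)
        if len(star) < config.min_species:
            trials.append(TrialRecord(t, seed_id, len(star), "low_coverage"))
            continue
        reps = select_representatives(star, rng)
        labels = sorted(reps)
        k = len(labels)
        mat = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                key = frozenset((reps[labels[i]], reps[labels[j]]))
                if key not in dist_cache:
                    dist_cache[key] = pairwise_distance(
                        sequences[reps[labels[i]]], sequences[reps[labels[j]]],
                        _aligner=aligner)
                mat[i, j] = mat[j, i] = dist_cache[key]
        if not mat.any():
            # all-zero distances: no phylogenetic signal, arbitrary topology
            trials.append(TrialRecord(t, seed_id, k, "degenerate"))
            continue
        gene_tree = neighbor_joining(DistanceMatrix(labels=labels, matrix=mat))
        if not gene_tree.splits():
            trials.append(TrialRecord(t, seed_id, k, "degenerate"))
            continue
        raw, scaled = rf_distance(gene_tree, unrooted_species)
        n_success += 1
        rf_sum += scaled
        trials.append(TrialRecord(t, seed_id, k, "success", raw, scaled))

    mean_rf = rf_sum / n_success if n_success else None
    return BenchmarkResult(n_trials=config.n_trials, n_success=n_success,
                           mean_scaled_rf=mean_rf, trials=trials)
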