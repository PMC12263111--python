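"""Core data model shared by all pipeline stages.

Coordinates are 0-based, half-open throughout; conversion to/from the 1-based
inclusive convention of GFF3 happens only at the file boundary (see
:mod:`orthoqc.io`).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "AnnotationSet",
    "ProteinRecord",
    "Proteome",
    "SpeciesTree",
    "TreeNode",
    "HOG",
    "HOGCollection",
    "OrthologPairs",
    "SpliceMap",
    "FormatError",
    "DataError",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX*")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class DataError(ValueError):
    """Input is well-formed but semantically inconsistent."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a sequence, with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A transcript: an ordered set of exon intervals on one chrom/strand."""

    id: str
    gene_id: str
    exons: Tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not self.exons:
            raise ValueError(f"transcript {self.id}: needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise FormatError(f"transcript {self.id}: exons on multiple chroms {chroms}")
        if len(strands) > 1:
            raise FormatError(f"transcript {self.id}: exons on mixed strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"transcript {self.id}: overlapping exons {a} / {b}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> Tuple[int, int]:
        return (self.exons[0].start, self.exons[-1].end)


@dataclass
class GeneModel:
    """A protein-coding gene with one or more transcripts."""

    id: str
    species: str
    transcripts: List[TranscriptModel]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.id}: needs >=1 transcript")
        for t in self.transcripts:
            if t.gene_id != self.id:
                raise ValueError(f"gene {self.id}: transcript {t.id} claims parent {t.gene_id}")
        if len({t.chrom for t in self.transcripts}) > 1:
            raise FormatError(f"gene {self.id}: transcripts on multiple chroms")


class AnnotationSet:
    """All protein-coding gene models of one species from one annotation source."""

    def __init__(self, label: str, species: str, genes: Iterable[GeneModel] = ()):
        self.label = label
        self.species = species
        self.genes: Dict[str, GeneModel] = {}
        seen_tx: set = set()
        for g in genes:
            if g.id in self.genes:
                raise FormatError(f"duplicate gene id {g.id}")
            for t in g.transcripts:
                if t.id in seen_tx:
                    raise FormatError(f"duplicate transcript id {t.id}")
                seen_tx.add(t.id)
            self.genes[g.id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self:
            yield from g.transcripts


@dataclass
class ProteinRecord:
    id: str
    gene_id: str
    species: str
    sequence: str
    canonical: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence.upper()) - AMINO_ACIDS
        if bad:
            raise FormatError(f"protein {self.id}: invalid residues {sorted(bad)}")

    @property
    def length(self) -> int:
        """Residue count, excluding a trailing stop symbol if present."""
        return len(self.sequence.rstrip("*"))


class Proteome:
    """The translated protein repertoire of one species from one source."""

    def __init__(self, label: str, species: str, proteins: Iterable[ProteinRecord] = ()):
        self.label = label
        self.species = species
        self.proteins: Dict[str, ProteinRecord] = {}
        for p in proteins:
            self.add(p)

    def add(self, p: ProteinRecord) -> None:
        if p.id in self.proteins:
            raise FormatError(f"duplicate protein id {p.id}")
        self.proteins[p.id] = p

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.proteins.values())

    def __contains__(self, pid: str) -> bool:
        return pid in self.proteins

    def __getitem__(self, pid: str) -> ProteinRecord:
        return self.proteins[pid]

    def canonical(self) -> List[ProteinRecord]:
        return [p for p in self if p.canonical]

    def by_gene(self) -> Dict[str, List[ProteinRecord]]:
        out: Dict[str, List[ProteinRecord]] = {}
        for p in self:
            out.setdefault(p.gene_id, []).append(p)
        return out


# --------------------------------------------------------------------------
# Species tree
# --------------------------------------------------------------------------

class TreeNode:
    """A node of a rooted species tree."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str, length: float = 0.0,
                 children: Optional[List["TreeNode"]] = None):
        self.label = label
        self.length = length
        self.children: List[TreeNode] = children or []
        self.parent: Optional[TreeNode] = None
        for c in self.children:
            c.parent = self

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted species tree; leaves are species, internal nodes named clades.

    Supports clade lookup (clade name -> species set), LCA queries and
    leaf-set restriction, which is all the metric modules need.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._nodes: Dict[str, TreeNode] = {}
        for n in self.postorder():
            if n.label in self._nodes:
                raise FormatError(f"duplicate node label {n.label!r} in species tree")
            self._nodes[n.label] = n

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        def walk(n: TreeNode) -> Iterator[TreeNode]:
            for c in n.children:
                yield from walk(c)
            yield n
        return walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    # -- queries -----------------------------------------------------------
    @property
    def leaf_labels(self) -> List[str]:
        return [n.label for n in self.postorder() if n.is_leaf]

    def node(self, label: str) -> TreeNode:
        try:
            return self._nodes[label]
        except KeyError:
            raise DataError(f"no node labeled {label!r} in species tree") from None

    def __contains__(self, label: str) -> bool:
        return label in self._nodes

    def clade(self, label: str) -> FrozenSet[str]:
        """Species below (and including, for a leaf) the named node."""
        node = self.node(label)
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            stack.extend(n.children)
        return frozenset(out)

    def lca(self, labels: Iterable[str]) -> TreeNode:
        labels = list(labels)
        if not labels:
            raise DataError("lca of empty label set")
        paths = []
        for lab in labels:
            n: Optional[TreeNode] = self.node(lab)
            path = []
            while n is not None:
                path.append(n)
                n = n.parent
            paths.append(list(reversed(path)))
        lca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            nodes = {id(p[depth]) for p in paths}
            if len(nodes) == 1:
                lca = paths[0][depth]
            else:
                break
        return lca

    def depth_to(self, label: str) -> float:
        """Sum of branch lengths from the root to the named node."""
        n = self.node(label)
        d = 0.0
        while n.parent is not None:
            d += n.length
            n = n.parent
        return d

    def newick(self, lengths: bool = True) -> str:
        def fmt(n: TreeNode) -> str:
            lab = n.label
            ln = f":{n.length:g}" if (lengths and n.parent is not None) else ""
            if n.is_leaf:
                return f"{lab}{ln}"
            return "(" + ",".join(fmt(c) for c in n.children) + f"){lab}{ln}"
        return fmt(self.root) + ";"

    def copy(self) -> "SpeciesTree":
        def clone(n: TreeNode) -> TreeNode:
            return TreeNode(n.label, n.length, [clone(c) for c in n.children])
        return SpeciesTree(clone(self.root))

    def restrict(self, keep: Iterable[str]) -> "SpeciesTree":
        """Return the tree restricted to a subset of leaves, with unary
        internal nodes suppressed (their branch lengths summed)."""
        keep = set(keep)
        missing = keep - set(self.leaf_labels)
        if missing:
            raise DataError(f"species not in tree: {sorted(missing)}")

        def prune(n: TreeNode) -> Optional[TreeNode]:
            if n.is_leaf:
                return TreeNode(n.label, n.length) if n.label in keep else None
            kids = [k for k in (prune(c) for c in n.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += n.length
                return kids[0]
            return TreeNode(n.label, n.length, kids)

        root = prune(self.root)
        if root is None:
            raise DataError("restriction removed every leaf")
        return SpeciesTree(root)


# --------------------------------------------------------------------------
# Hierarchical orthologous groups
# --------------------------------------------------------------------------

@dataclass
class HOG:
    """A (possibly nested) hierarchical orthologous group.

    ``members`` are (species, gene_id) pairs of all extant genes in the
    group; children partition the members further. ``paralog`` marks groups
    whose children descend from a duplication rather than a speciation.
    """

    id: str
    level: str
    members: Tuple[Tuple[str, str], ...]
    children: Tuple["HOG", ...] = ()
    paralog: bool = False

    def profile(self) -> Counter:
        return Counter(sp for sp, _ in self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    def validate_nesting(self) -> None:
        mem = set(self.members)
        for c in self.children:
            if not set(c.members) <= mem:
                raise DataError(f"HOG {c.id}: members not a subset of parent {self.id}")
            c.validate_nesting()


class HOGCollection:
    """Top-level (root) HOGs plus their phyletic profiles."""

    def __init__(self, roothogs: Iterable[HOG] = (),
                 profiles: Optional[Mapping[str, Mapping[str, int]]] = None,
                 species: Optional[Sequence[str]] = None):
        self.roothogs: List[HOG] = list(roothogs)
        if profiles is not None:
            self.profiles: Dict[str, Counter] = {
                hid: Counter({sp: c for sp, c in prof.items() if c})
                for hid, prof in profiles.items()
            }
        else:
            self.profiles = {h.id: h.profile() for h in self.roothogs}
        if species is not None:
            self.species = list(species)
        else:
            sp: set = set()
            for prof in self.profiles.values():
                sp.update(prof)
            self.species = sorted(sp)

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[HOG]:
        return iter(self.roothogs)


# --------------------------------------------------------------------------
# Pairwise orthologs
# --------------------------------------------------------------------------

class OrthologPairs:
    """An unordered set of cross-species orthologous protein pairs."""

    def __init__(self, species_of: Optional[Mapping[str, str]] = None):
        self._pairs: set = set()
        self.species_of = dict(species_of) if species_of is not None else None

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise DataError(f"self-pair {a!r}")
        if self.species_of is not None:
            sa, sb = self.species_of.get(a), self.species_of.get(b)
            if sa is not None and sa == sb:
                raise DataError(f"within-species pair ({a}, {b}) in species {sa}")
        self._pairs.add(frozenset((a, b)))

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair) -> bool:
        a, b = pair
        return frozenset((a, b)) in self._pairs

    def __iter__(self) -> Iterator[Tuple[str, str]]:
        for p in self._pairs:
            a, b = sorted(p)
            yield a, b

    def ids(self) -> set:
        return set(itertools.chain.from_iterable(self._pairs))

    def partners(self, pid: str) -> set:
        out = set()
        for p in self._pairs:
            if pid in p:
                out.update(p - {pid})
        return out

    def partner_index(self) -> Dict[str, set]:
        """id -> set of partner ids, built in one pass."""
        idx: Dict[str, set] = {}
        for p in self._pairs:
            a, b = tuple(p)
            idx.setdefault(a, set()).add(b)
            idx.setdefault(b, set()).add(a)
        return idx

    def __eq__(self, other) -> bool:
        return isinstance(other, OrthologPairs) and self._pairs == other._pairs


class SpliceMap(dict):
    """gene id -> ordered list of isoform protein ids."""

    def validate(self, proteome: Proteome) -> None:
        seen: Dict[str, str] = {}
        for gene, isoforms in self.items():
            for iso in isoforms:
                if iso not in proteome:
                    raise DataError(f"splice map lists unknown isoform {iso!r} for gene {gene!r}")
                if iso in seen:
                    raise DataError(f"isoform {iso!r} listed for both {seen[iso]!r} and {gene!r}")
                seen[iso] = gene
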