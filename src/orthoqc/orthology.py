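"""Ortholog-proportion and HOG quality metrics.

All per-proteome statistics operate on canonical isoforms only: one protein
per gene, here the longest isoform (ties broken by smallest protein id).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .model import (
    DataError,
    HOG,
    HOGCollection,
    OrthologPairs,
    Proteome,
    ProteinRecord,
    SpeciesTree,
    SpliceMap,
)

__all__ = [
    "OrthologProportion",
    "PhyleticPattern",
    "HOGMetrics",
    "select_canonical_longest",
    "ortholog_proportion",
    "hog_sizes",
    "hog_completeness",
    "collection_completeness",
    "count_pattern",
    "hogs_from_pairs",
]

WILDCARD = "*"


@dataclass
class OrthologProportion:
    """Per-species summary of canonical proteins with >=1 ortholog."""

    species: str
    n_canonical: int
    n_with_ortholog: int
    singletons: FrozenSet[str]

    def __post_init__(self) -> None:
        assert self.n_with_ortholog + len(self.singletons) == self.n_canonical

    @property
    def proportion(self) -> float:
        if self.n_canonical == 0:
            return 0.0
        return self.n_with_ortholog / self.n_canonical


@dataclass(frozen=True)
class PhyleticPattern:
    """Expected copy count per species; the wildcard ``"*"`` matches any.

    ``default`` is the count required of species not listed explicitly
    (itself possibly the wildcard).
    """

    counts: Tuple[Tuple[str, object], ...]
    default: object = WILDCARD

    @classmethod
    def make(cls, counts: Mapping[str, object], default: object = WILDCARD
             ) -> "PhyleticPattern":
        for sp, c in counts.items():
            if c != WILDCARD and (not isinstance(c, int) or c < 0):
                raise ValueError(f"pattern count for {sp!r} must be >=0 or '*'")
        if default != WILDCARD and (not isinstance(default, int) or default < 0):
            raise ValueError("pattern default must be >=0 or '*'")
        return cls(counts=tuple(sorted(counts.items())), default=default)

    def expected(self, species: str) -> object:
        for sp, c in self.counts:
            if sp == species:
                return c
        return self.default

    def species(self) -> List[str]:
        return [sp for sp, _ in self.counts]


@dataclass
class HOGMetrics:
    """Collection-level HOG summaries."""

    n_roothogs: int
    size_distribution: Counter
    completeness: Dict[str, float] = field(default_factory=dict)
    pattern_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def mean_completeness(self) -> Optional[float]:
        if not self.completeness:
            return None
        return sum(self.completeness.values()) / len(self.completeness)


# --------------------------------------------------------------------------
# Canonicalization
# --------------------------------------------------------------------------

def select_canonical_longest(proteome: Proteome,
                             splice: Optional[SpliceMap] = None) -> Proteome:
    """Flag one canonical isoform per gene: the longest, ties broken by the
    lexicographically smallest protein id.

    When a splice map is given, a gene's candidate isoforms are restricted
    to the ones it lists; genes absent from the map keep all their proteins
    as candidates (for single-protein genes that protein is canonical).
    """
    if splice is not None:
        splice.validate(proteome)
    out = Proteome(label=proteome.label, species=proteome.species)
    for gene_id, prots in proteome.by_gene().items():
        if splice is not None and gene_id in splice:
            candidates = [p for p in prots if p.id in set(splice[gene_id])]
        else:
            candidates = list(prots)
        if not candidates:
            raise DataError(f"gene {gene_id!r}: no isoforms left after splice-map filtering")
        best = min(candidates, key=lambda p: (-p.length, p.id))
        for p in prots:
            out.add(ProteinRecord(id=p.id, gene_id=p.gene_id, species=p.species,
                                  sequence=p.sequence, canonical=(p.id == best.id)))
    return out


# --------------------------------------------------------------------------
# Ortholog proportion
# --------------------------------------------------------------------------

def ortholog_proportion(proteome: Proteome, pairs: OrthologPairs,
                        all_isoforms: bool = False) -> OrthologProportion:
    """Fraction of the species' canonical proteins appearing in >=1 pair.

    Pair ids touching this species must resolve to canonical proteins of the
    proteome (``all_isoforms=True`` relaxes the denominator to every
    protein, for sensitivity analysis).
    """
    if all_isoforms:
        universe = {p.id for p in proteome}
    else:
        universe = {p.id for p in proteome.canonical()}
        if not universe:
            raise DataError(f"proteome {proteome.label!r}/{proteome.species!r} "
                            f"has no canonical proteins; canonicalize first")
    offenders = sorted(
        pid for pid in pairs.ids()
        if pid in proteome and pid not in universe
    )
    if offenders:
        raise DataError(f"pair ids not canonical in {proteome.species!r}: "
                        f"{offenders[:10]}{'...' if len(offenders) > 10 else ''}")
    paired = pairs.ids() & universe
    singletons = frozenset(universe - paired)
    return OrthologProportion(species=proteome.species,
                              n_canonical=len(universe),
                              n_with_ortholog=len(paired),
                              singletons=singletons)


# --------------------------------------------------------------------------
# HOG metrics
# --------------------------------------------------------------------------

def hog_sizes(hogs: HOGCollection) -> HOGMetrics:
    """Root-HOG count and size distribution (genes per rootHOG; duplicated
    genes within a species contribute their copy count)."""
    sizes = Counter()
    for hid, prof in hogs.profiles.items():
        sizes[sum(prof.values())] += 1
    return HOGMetrics(n_roothogs=len(hogs.profiles), size_distribution=sizes)


def hog_completeness(hog: HOG, tree: SpeciesTree) -> float:
    """Species represented in the HOG / species in the clade it is defined at."""
    clade = tree.clade(hog.level)
    present = {sp for sp, _ in hog.members}
    outside = present - clade
    if outside:
        raise DataError(f"HOG {hog.id}: members outside level {hog.level!r}: "
                        f"{sorted(outside)}")
    return len(present) / len(clade)


def collection_completeness(hogs: HOGCollection, tree: SpeciesTree) -> Dict[str, float]:
    return {h.id: hog_completeness(h, tree) for h in hogs.roothogs}


def count_pattern(hogs: HOGCollection, pattern: PhyleticPattern) -> int:
    """Count rootHOGs whose phyletic profile equals the pattern on every
    non-wildcard species (species absent from a profile count 0)."""
    unknown = [sp for sp in pattern.species() if sp not in hogs.species]
    if unknown:
        raise DataError(f"pattern species not in dataset: {unknown}")
    count = 0
    for prof in hogs.profiles.values():
        ok = True
        for sp in hogs.species:
            want = pattern.expected(sp)
            if want != WILDCARD and prof.get(sp, 0) != want:
                ok = False
                break
        # profiles may mention species outside hogs.species only if wildcarded
        if ok:
            for sp in prof:
                if sp not in hogs.species and pattern.default != WILDCARD \
                        and prof[sp] != pattern.default:
                    ok = False
                    break
        if ok:
            count += 1
    return count


# --------------------------------------------------------------------------
# Grouping observed pairs into flat HOGs
# --------------------------------------------------------------------------

def hogs_from_pairs(pairs: OrthologPairs, species_of: Mapping[str, str],
                    tree: Optional[SpeciesTree] = None,
                    prefix: str = "OG") -> HOGCollection:
    """Group an ortholog-pair graph into flat rootHOGs.

    Connected components with >=2 members become rootHOGs; the level of a
    group is the species-tree clade of the LCA of its member species (or
    empty without a tree). This is the graph-level analogue of a
    hierarchical group inference and is used to summarize observed pairs
    when no OrthoXML is available.
    """
    parent: Dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    comps: Dict[str, List[str]] = {}
    for pid in parent:
        comps.setdefault(find(pid), []).append(pid)

    roothogs = []
    for i, root in enumerate(sorted(comps), 1):
        members = sorted(comps[root])
        if len(members) < 2:
            continue
        sp_set = {species_of[m] for m in members}
        level = tree.lca(sp_set).label if tree is not None else ""
        roothogs.append(HOG(id=f"{prefix}{i:05d}", level=level,
                            members=tuple((species_of[m], m) for m in members)))
    return HOGCollection(roothogs=roothogs)
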