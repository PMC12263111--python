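"""Gene-model agreement between two annotations of the same assembly.

Two transcripts are a *complete match* when they lie on the same chromosome
and strand and have identical intron chains; the outer boundaries of the
first and last exon are free, so terminal-exon extensions or truncations
that preserve every splice site still match. For mono-exonic transcripts,
where the intron-chain criterion is vacuous, any exon overlap counts.

Gene-level agreement is summarized by a symmetric Jaccard-style index:
ji = (matched query genes + matched reference genes) / (query genes +
reference genes). One-to-many matches count every gene involved on both
sides, so the index handles asymmetric matchings naturally and equals 1 on
identical annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .model import AnnotationSet, GenomicInterval, TranscriptModel

__all__ = [
    "IntronChain",
    "AgreementStats",
    "intron_chain",
    "classify_match",
    "gene_agreement",
    "pairwise_agreement",
]


@dataclass(frozen=True)
class IntronChain:
    """The ordered intron intervals of a transcript plus its span."""

    chrom: str
    strand: str
    introns: Tuple[Tuple[int, int], ...]
    span: Tuple[int, int]

    @property
    def is_mono_exonic(self) -> bool:
        return not self.introns


@dataclass
class AgreementStats:
    n_query: int
    n_ref: int
    matched_query: FrozenSet[str]
    matched_ref: FrozenSet[str]

    @property
    def ji(self) -> float:
        denom = self.n_query + self.n_ref
        if denom == 0:
            return 0.0
        return (len(self.matched_query) + len(self.matched_ref)) / denom


def intron_chain(transcript: TranscriptModel) -> IntronChain:
    """Introns are the gaps between consecutive exons; a mono-exonic
    transcript yields an empty chain carrying only the span."""
    introns = tuple(
        (a.end, b.start) for a, b in zip(transcript.exons, transcript.exons[1:])
    )
    return IntronChain(chrom=transcript.chrom, strand=transcript.strand,
                       introns=introns, span=transcript.span)


def classify_match(query: TranscriptModel, ref: TranscriptModel) -> str:
    """Return ``"complete"`` or ``"no_match"`` for a transcript pair."""
    q, r = intron_chain(query), intron_chain(ref)
    if q.chrom != r.chrom or q.strand != r.strand:
        return "no_match"
    if q.is_mono_exonic != r.is_mono_exonic:
        return "no_match"
    if q.is_mono_exonic:
        # intron identity is vacuous: require any shared base
        if q.span[0] < r.span[1] and r.span[0] < q.span[1]:
            return "complete"
        return "no_match"
    return "complete" if q.introns == r.introns else "no_match"


def _match_index(annotation: AnnotationSet):
    """Index transcripts for complete-match lookup.

    Multi-exonic transcripts are keyed by their full intron chain (the match
    criterion is exact chain identity, so a hash join is equivalent to
    all-pairs comparison). Mono-exonic transcripts are kept as per-
    (chrom, strand) interval lists for overlap queries.
    """
    multi: Dict[Tuple, Set[str]] = {}
    mono: Dict[Tuple[str, str], List[Tuple[int, int, str]]] = {}
    for gene in annotation:
        for t in gene.transcripts:
            chain = intron_chain(t)
            if chain.is_mono_exonic:
                mono.setdefault((chain.chrom, chain.strand), []).append(
                    (chain.span[0], chain.span[1], gene.id))
            else:
                key = (chain.chrom, chain.strand, chain.introns)
                multi.setdefault(key, set()).add(gene.id)
    return multi, mono


def gene_agreement(query: AnnotationSet, ref: AnnotationSet) -> AgreementStats:
    """Gene-level complete-match agreement between two annotations.

    A gene is matched iff any of its transcripts is a complete match to any
    transcript of any gene on the other side.
    """
    if len(query) == 0 or len(ref) == 0:
        warnings.warn("empty annotation set: agreement index defined as 0")
        return AgreementStats(n_query=len(query), n_ref=len(ref),
                              matched_query=frozenset(), matched_ref=frozenset())

    ref_multi, ref_mono = _match_index(ref)
    matched_query: Set[str] = set()
    matched_ref: Set[str] = set()
    for gene in query:
        for t in gene.transcripts:
            chain = intron_chain(t)
            if chain.is_mono_exonic:
                for (start, end, ref_gene) in ref_mono.get((chain.chrom, chain.strand), ()):
                    if chain.span[0] < end and start < chain.span[1]:
                        matched_query.add(gene.id)
                        matched_ref.add(ref_gene)
            else:
                hits = ref_multi.get((chain.chrom, chain.strand, chain.introns))
                if hits:
                    matched_query.add(gene.id)
                    matched_ref.update(hits)
    return AgreementStats(n_query=len(query), n_ref=len(ref),
                          matched_query=frozenset(matched_query),
                          matched_ref=frozenset(matched_ref))


def pairwise_agreement(
    sets: Mapping[str, Mapping[str, AnnotationSet]],
) -> pd.DataFrame:
    """All-pairs agreement between annotation methods, per species.

    ``sets`` maps method label -> species -> annotation. Each method pair is
    evaluated twice per shared species, swapping the query/reference roles,
    and the two index values averaged. Species present in only one method of
    a pair are skipped with a warning.

    Returns a table with columns: species, method_pair, n_query, n_ref,
    matched_query, matched_ref, ji_dir1, ji_dir2, ji_mean.
    """
    methods = sorted(sets)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    rows = []
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            shared = sorted(set(sets[ma]) & set(sets[mb]))
            skipped = sorted(set(sets[ma]) ^ set(sets[mb]))
            if skipped:
                warnings.warn(f"{ma} vs {mb}: species {skipped} present in "
                              f"only one method; skipped")
            for sp in shared:
                s1 = gene_agreement(sets[ma][sp], sets[mb][sp])
                s2 = gene_agreement(sets[mb][sp], sets[ma][sp])
                rows.append({
                    "species": sp,
                    "method_pair": f"{ma}|{mb}",
                    "n_query": s1.n_query,
                    "n_ref": s1.n_ref,
                    "matched_query": len(s1.matched_query),
                    "matched_ref": len(s1.matched_ref),
                    "ji_dir1": s1.ji,
                    "ji_dir2": s2.ji,
                    "ji_mean": (s1.ji + s2.ji) / 2.0,
                })
    return pd.DataFrame(rows, columns=["species", "method_pair", "n_query",
                                       "n_ref", "matched_query", "matched_ref",
                                       "ji_dir1", "ji_dir2", "ji_mean"])
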