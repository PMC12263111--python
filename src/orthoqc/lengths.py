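"""Protein-length diagnostics.

Median lengths per species, two-sample Kolmogorov-Smirnov distances between
species' length distributions (the statistic D is used as a distance; 0 =
identical distributions, 1 = maximal dissimilarity), with-ortholog versus
singleton splits, and Pearson correlations against ortholog proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import DataError, Proteome
from .orthology import OrthologProportion

__all__ = [
    "LengthSample",
    "KSMatrix",
    "median_length",
    "ks_statistic",
    "ks_matrix",
    "split_by_orthology",
    "pearson_r",
]


@dataclass
class LengthSample:
    """A labeled multiset of protein lengths (amino acids)."""

    label: str
    lengths: np.ndarray

    def __init__(self, label: str, lengths: Sequence[int]):
        self.label = label
        self.lengths = np.asarray(lengths, dtype=int)
        if len(self.lengths) and self.lengths.min() < 1:
            raise ValueError(f"{label}: lengths must be >= 1")

    def __len__(self) -> int:
        return len(self.lengths)

    @classmethod
    def from_proteome(cls, proteome: Proteome, canonical_only: bool = True
                      ) -> "LengthSample":
        prots = proteome.canonical() if canonical_only else list(proteome)
        return cls(proteome.species, [p.length for p in prots])


@dataclass
class KSMatrix:
    labels: List[str]
    matrix: np.ndarray

    @property
    def average(self) -> float:
        """Mean KS statistic over unordered label pairs."""
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return float(self.matrix[iu].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def median_length(sample: LengthSample) -> float:
    """Median length; for even n, the mean of the two central order statistics."""
    if len(sample) == 0:
        raise DataError(f"median of empty sample {sample.label!r}")
    return float(np.median(sample.lengths))


def ks_statistic(a: LengthSample, b: LengthSample) -> float:
    """Two-sample KS statistic D = sup_x |F_a(x) - F_b(x)|."""
    if len(a) == 0 or len(b) == 0:
        raise DataError("KS statistic of empty sample")
    return float(stats.ks_2samp(a.lengths, b.lengths, method="asymp").statistic)


def ks_matrix(samples: Sequence[LengthSample]) -> KSMatrix:
    """All pairwise KS statistics between the given samples."""
    if len(samples) < 2:
        raise ValueError("need >=2 samples")
    n = len(samples)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ks_statistic(samples[i], samples[j])
            mat[i, j] = mat[j, i] = d
    return KSMatrix(labels=[s.label for s in samples], matrix=mat)


def split_by_orthology(proteome: Proteome, proportion: OrthologProportion
                       ) -> Tuple[LengthSample, LengthSample]:
    """Partition canonical protein lengths into (with-ortholog, singleton)."""
    canonical = {p.id: p for p in proteome.canonical()}
    if proportion.species != proteome.species:
        raise DataError(f"species mismatch: {proportion.species!r} vs "
                        f"{proteome.species!r}")
    unknown = proportion.singletons - set(canonical)
    if unknown or proportion.n_canonical != len(canonical):
        raise DataError("ortholog proportion was not computed from this proteome")
    singles = sorted(proportion.singletons)
    withs = sorted(set(canonical) - proportion.singletons)
    return (
        LengthSample(f"{proteome.species}:with_ortholog",
                     [canonical[i].length for i in withs]),
        LengthSample(f"{proteome.species}:singleton",
                     [canonical[i].length for i in singles]),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two paired series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired series must have equal length")
    if len(x) < 3:
        raise DataError("Pearson correlation needs >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("Pearson correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)
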