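"""Alignment divergence statistics: site classes, diversity, p-distances.

Site statistics (S, parsimony-informative sites, nucleotide diversity)
use complete deletion — any column containing a gap or N is excluded —
while pairwise distances use pairwise deletion, mirroring the defaults of
the tools these statistics are conventionally computed with (DnaSP and
MEGA respectively). Ambiguity codes other than N are treated as N by the
readers upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AlignmentMatrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

EXCLUDED, INVARIANT, VARIABLE, PARSIMONY_INFORMATIVE = (
    "excluded", "invariant", "variable", "parsimony-informative",
)


@dataclass
class ColumnClasses:
    """Per-column labels; parsimony-informative columns are also variable."""

    labels: np.ndarray  # dtype object/str, length = alignment length

    @property
    def excluded(self) -> np.ndarray:
        return self.labels == EXCLUDED

    @property
    def variable(self) -> np.ndarray:
        return (self.labels == VARIABLE) | (self.labels == PARSIMONY_INFORMATIVE)

    @property
    def parsimony_informative(self) -> np.ndarray:
        return self.labels == PARSIMONY_INFORMATIVE


@dataclass
class RegionStats:
    """Summary of one column set: raw and analyzed sites, S, PI, and π."""

    sites: int            # columns considered (gapped columns included)
    analyzed_sites: int   # columns surviving complete deletion
    S: int                # variable sites
    PI: int               # parsimony-informative sites
    pi: float             # nucleotide diversity (mean pairwise p-distance)


@dataclass
class DistanceMatrix:
    """Pairwise p-distance and nucleotide-difference counts (pairwise deletion)."""

    ids: list[str]
    p_distance: np.ndarray  # float, symmetric, zero diagonal
    n_diff: np.ndarray      # int, symmetric, zero diagonal


def _base_counts(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column counts of A,C,G,T (shape (4, L)) and the excluded mask."""
    counts = np.vstack([(mat == b).sum(axis=0) for b in _BASES])
    excluded = counts.sum(axis=0) != mat.shape[0]  # any gap/N in column
    return counts, excluded


def column_classes(alignment: AlignmentMatrix) -> ColumnClasses:
    """Classify every column as excluded / invariant / variable / PI.

    Excluded: any row has '-' or 'N'. Variable: >=2 distinct bases.
    Parsimony-informative: >=2 distinct bases each present in >=2 rows.
    """
    counts, excluded = _base_counts(alignment.matrix)
    n_distinct = (counts > 0).sum(axis=0)
    n_ge2 = (counts >= 2).sum(axis=0)
    labels = np.full(alignment.length, INVARIANT, dtype=object)
    labels[n_distinct >= 2] = VARIABLE
    labels[(n_distinct >= 2) & (n_ge2 >= 2)] = PARSIMONY_INFORMATIVE
    labels[excluded] = EXCLUDED
    return ColumnClasses(labels)


def diversity_stats(
    alignment: AlignmentMatrix, column_subset: np.ndarray | None = None
) -> RegionStats:
    """S, PI, and nucleotide diversity π over a column set (complete deletion).

    π = Σ_{i<j} d_ij / C(n,2) where d_ij is the p-distance of rows i, j
    restricted to the analyzed (gap- and N-free) columns of the subset;
    equivalently the per-column mean pairwise difference fraction.
    """
    mat = alignment.matrix
    if column_subset is not None:
        mat = mat[:, column_subset]
    n, total_cols = mat.shape
    counts, excluded = _base_counts(mat)
    keep = ~excluded
    analyzed = int(keep.sum())
    if analyzed == 0:
        raise ValueError("no analyzable columns (all contain gaps or N)")
    counts = counts[:, keep]
    n_distinct = (counts > 0).sum(axis=0)
    n_ge2 = (counts >= 2).sum(axis=0)
    S = int((n_distinct >= 2).sum())
    PI = int(((n_distinct >= 2) & (n_ge2 >= 2)).sum())
    pairs = n * (n - 1) // 2
    same_pairs = (counts * (counts - 1) // 2).sum(axis=0)
    diff_pairs = pairs - same_pairs
    pi = float(diff_pairs.sum() / (pairs * analyzed))
    return RegionStats(sites=total_cols, analyzed_sites=analyzed, S=S, PI=PI, pi=pi)


def distance_matrix(alignment: AlignmentMatrix) -> DistanceMatrix:
    """Pairwise nucleotide differences and p-distance under pairwise deletion."""
    mat = alignment.matrix
    n = mat.shape[0]
    unamb = np.isin(mat, _BASES)
    p = np.zeros((n, n), dtype=float)
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = unamb[i] & unamb[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"pair ({alignment.ids[i]!r}, {alignment.ids[j]!r}): "
                    "no comparable columns"
                )
            ndiff = int((mat[i][both] != mat[j][both]).sum())
            d[i, j] = d[j, i] = ndiff
            p[i, j] = p[j, i] = ndiff / compared
    return DistanceMatrix(list(alignment.ids), p, d)
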