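"""Sørensen-family β-diversity partitioning into turnover and nestedness.

For a pair of sites with ``a`` shared species and ``b``/``c`` species unique
to each side, total dissimilarity βsor = (b+c)/(2a+b+c) decomposes additively
into a replacement (turnover) component βsim = min(b,c)/(a+min(b,c)) and a
nestedness-resultant component βsne = βsor − βsim. The multiple-site forms
aggregate the pairwise one-sided unique-species counts across all pairs, so
that richness-difference (nestedness) and replacement signals are separated
for a whole set of sites at once. Temporal change is the same pairwise
partition applied to one site's composition in two survey years.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .community import CommunityMatrix
from .errors import DomainError, MatchingError, ValidationError

__all__ = [
    "PairCounts",
    "BetaPartition",
    "pair_counts",
    "pairwise_partition",
    "multisite_partition",
    "temporal_partition",
    "component_distance_matrix",
    "average_linkage_cluster",
    "Dendrogram",
]


@dataclass(frozen=True)
class PairCounts:
    """Shared (a) and one-sided unique (b, c) species counts for a site pair."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise DomainError("pair counts must be non-negative")
        if self.a + self.b == 0 or self.a + self.c == 0:
            raise DomainError("cannot partition dissimilarity involving an empty site")


@dataclass(frozen=True)
class BetaPartition:
    """The additive triple (βsor, βsim, βsne); βsor = βsim + βsne."""

    bsor: float
    bsim: float
    bsne: float

    def component(self, which: str) -> float:
        return {"bsor": self.bsor, "bsim": self.bsim, "bsne": self.bsne}[which]


def _as_incidence_array(matrix) -> np.ndarray:
    if isinstance(matrix, CommunityMatrix):
        arr = matrix.incidence().values.to_numpy(dtype=bool)
    else:
        arr = np.asarray(matrix)
        arr = arr > 0
    if arr.ndim != 2:
        raise DomainError("incidence input must be 2-dimensional (sites x species)")
    return arr


def pair_counts(site1, site2) -> PairCounts:
    """Exact set-arithmetic counts (a, b, c) from two incidence vectors."""
    v1 = np.asarray(site1) > 0
    v2 = np.asarray(site2) > 0
    if v1.shape != v2.shape:
        raise DomainError("incidence vectors must cover the same species list")
    if not v1.any() and not v2.any():
        raise DomainError("both sites are empty")
    a = int(np.count_nonzero(v1 & v2))
    b = int(np.count_nonzero(v1 & ~v2))
    c = int(np.count_nonzero(~v1 & v2))
    return PairCounts(a, b, c)


def pairwise_partition(counts: PairCounts) -> BetaPartition:
    """Partition pairwise Sørensen dissimilarity into turnover and nestedness."""
    a, b, c = counts.a, counts.b, counts.c
    denom = 2 * a + b + c
    if denom == 0:
        raise DomainError("2a+b+c = 0: no species in either site")
    bsor = (b + c) / denom
    m = min(b, c)
    bsim = m / (a + m) if (a + m) > 0 else 0.0
    return BetaPartition(bsor, bsim, bsor - bsim)


def multisite_partition(matrix) -> BetaPartition:
    """Multiple-site Sørensen partition over n ≥ 2 sites.

    With Si the richness of site i, ST the pooled richness, and bij/bji the
    one-sided unique counts of each unordered pair:

        βSIM = Σ min(bij,bji) / (Σ min(bij,bji) + ΣSi − ST)
        βSOR = (Σ min + Σ max) / (2(ΣSi − ST) + Σ min + Σ max)
        βSNE = βSOR − βSIM

    For n = 2 this reduces exactly to the pairwise partition.
    """
    inc = _as_incidence_array(matrix)
    n = inc.shape[0]
    if n < 2:
        raise DomainError("multiple-site partition needs at least 2 sites")
    richness = inc.sum(axis=1)
    if (richness == 0).any():
        empty = np.flatnonzero(richness == 0)
        labels = (
            [matrix.values.index[i] for i in empty]
            if isinstance(matrix, CommunityMatrix)
            else list(empty)
        )
        raise DomainError(f"empty site(s): {labels}")
    pooled = int(inc.any(axis=0).sum())
    # shared-overlap term ΣSi − ST and the pairwise one-sided unique counts
    shared_total = int(richness.sum()) - pooled
    sum_min = 0
    sum_max = 0
    for i, j in combinations(range(n), 2):
        bij = int(np.count_nonzero(inc[i] & ~inc[j]))
        bji = int(np.count_nonzero(inc[j] & ~inc[i]))
        sum_min += min(bij, bji)
        sum_max += max(bij, bji)
    bsim = sum_min / (sum_min + shared_total) if (sum_min + shared_total) > 0 else 0.0
    denom = 2 * shared_total + sum_min + sum_max
    bsor = (sum_min + sum_max) / denom if denom > 0 else 0.0
    return BetaPartition(bsor, bsim, bsor - bsim)


def _siteless_key(matrix: CommunityMatrix) -> pd.Index:
    meta = matrix.sites
    cols = [c for c in ("summit_id", "aspect", "quadrat_index") if c in meta.columns]
    keys = meta[cols].apply(
        lambda r: ":".join("" if pd.isna(v) else str(v) for v in r), axis=1
    )
    return pd.Index(keys)


def temporal_partition(
    matrix_t1: CommunityMatrix, matrix_t2: CommunityMatrix
) -> dict[str, BetaPartition]:
    """Per-site partition of between-survey dissimilarity.

    Sites are matched on (summit, aspect[, quadrat]); every site must be
    present in both years. Returns a mapping from the year-free site key to
    its temporal BetaPartition.
    """
    species = sorted(set(matrix_t1.species) | set(matrix_t2.species))
    inc1 = matrix_t1.incidence().values.reindex(columns=species, fill_value=0.0)
    inc2 = matrix_t2.incidence().values.reindex(columns=species, fill_value=0.0)
    keys1 = _siteless_key(matrix_t1)
    keys2 = _siteless_key(matrix_t2)
    orphans = sorted(set(keys1).symmetric_difference(keys2))
    if orphans or keys1.has_duplicates or keys2.has_duplicates:
        raise MatchingError(f"sites not matched one-to-one across years; orphans: {orphans}")
    inc2 = inc2.set_axis(list(keys2), axis=0).loc[list(keys1)]
    out: dict[str, BetaPartition] = {}
    for key, row1, row2 in zip(keys1, inc1.to_numpy(), inc2.to_numpy()):
        out[key] = pairwise_partition(pair_counts(row1, row2))
    return out


def component_distance_matrix(
    matrix: CommunityMatrix, component: Literal["bsor", "bsim", "bsne"] = "bsor"
) -> pd.DataFrame:
    """Square symmetric matrix of one pairwise-partition component."""
    inc = _as_incidence_array(matrix)
    labels = list(matrix.values.index) if isinstance(matrix, CommunityMatrix) else list(range(len(inc)))
    if len(inc) < 2:
        raise DomainError("need at least 2 sites")
    out = np.zeros((len(inc), len(inc)))
    for i, j in combinations(range(len(inc)), 2):
        part = pairwise_partition(pair_counts(inc[i], inc[j]))
        out[i, j] = out[j, i] = part.component(component)
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix plus ordered leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic(self) -> pd.DataFrame:
        from scipy.cluster.hierarchy import cophenet

        dense = squareform(cophenet(self.linkage))
        return pd.DataFrame(dense, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        """Nested-parenthesis tree text with ultrametric branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def quote(label: str) -> str:
            if any(ch in label for ch in "():,;[] \t'"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def walk(node) -> str:
            if node.is_leaf():
                return quote(self.labels[node.id])
            # height stored on the merge; children branch length = parent h/2 - child h/2
            left = walk(node.left)
            right = walk(node.right)
            bl_left = node.dist / 2 - (0.0 if node.left.is_leaf() else node.left.dist / 2)
            bl_right = node.dist / 2 - (0.0 if node.right.is_leaf() else node.right.dist / 2)
            return f"({left}:{bl_left:.10g},{right}:{bl_right:.10g})"

        return walk(tree) + ";"


def average_linkage_cluster(dissimilarity: pd.DataFrame | np.ndarray) -> Dendrogram:
    """UPGMA agglomeration of a symmetric zero-diagonal dissimilarity matrix.

    Sites are pre-sorted lexicographically by label so that ties in merge
    distance break deterministically.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        labels = [str(x) for x in dissimilarity.index]
        arr = dissimilarity.to_numpy(dtype=float)
    else:
        arr = np.asarray(dissimilarity, dtype=float)
        labels = [str(i) for i in range(arr.shape[0])]
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("dissimilarity must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValidationError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValidationError("dissimilarity must have a zero diagonal")
    if (arr < 0).any():
        raise ValidationError("dissimilarity must be non-negative")
    order = np.argsort(np.asarray(labels, dtype=object))
    labels = [labels[i] for i in order]
    arr = arr[np.ix_(order, order)]
    condensed = squareform(arr, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    return Dendrogram(link, labels)
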