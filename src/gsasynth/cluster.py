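"""Agglomerative hierarchical clustering of terms and partition diagnostics.

Agglomeration (single / complete / average linkage) is delegated to
``scipy.cluster.hierarchy``; the diagnostics the pipeline reports are
implemented here:

* **CCC** — cophenetic correlation coefficient: Pearson correlation between
  the original pairwise distances and the dendrogram's cophenetic distances.
* **Z-index** — normalized co-clustering disagreement between two dendrograms,
  accumulated over every non-trivial cut level k = 2 .. n-1; 0 for identical
  trees, 1 for complete dissemblance.
* **Silhouette / ASW** — per-item silhouette width and its average, used to
  pick the optimal number of clusters from dendrogram cuts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError

LINKAGES = ("single", "complete", "average")

#: interpretive ASW bands: below 0.25 likely artificial structure, above 0.50 strong
ASW_THRESHOLDS = (0.25, 0.50)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over an ordered leaf set."""

    leaves: tuple[str, ...]
    merges: np.ndarray  # scipy linkage matrix, shape (n-1, 4)
    linkage: str

    @property
    def n(self) -> int:
        return len(self.leaves)

    def cut(self, k: int) -> "Partition":
        """Flat partition into exactly k clusters.

        The first n - k merges are applied in agglomeration order, so exactly
        k clusters remain even when merge heights are tied.  Labels are
        contiguous from 1, ordered by each cluster's first leaf.
        """
        n = self.n
        if not 1 <= k <= n:
            raise ValidationError(f"k={k} outside [1, {n}]")
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for step in range(n - k):
            a, b = int(self.merges[step, 0]), int(self.merges[step, 1])
            members[n + step] = members.pop(a) + members.pop(b)
        clusters = sorted(members.values(), key=min)
        out: dict[str, int] = {}
        for label, leaf_idx in enumerate(clusters, start=1):
            for i in leaf_idx:
                out[self.leaves[i]] = label
        return Partition(assignment=out, k=k)

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.merges)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return render(tree, tree.dist) + ";"


@dataclass(frozen=True)
class Partition:
    assignment: dict[str, int]
    k: int

    def labels_for(self, order: tuple[str, ...]) -> np.ndarray:
        return np.array([self.assignment[t] for t in order], dtype=int)


def _validate_distance(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise ValidationError("distance matrix must be square with >= 2 items")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValidationError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValidationError("distance matrix must be nonnegative")
    return d


def agglomerate(d: np.ndarray, leaves: list[str], linkage: str) -> Dendrogram:
    """Hierarchical agglomeration of a precomputed distance matrix."""
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}")
    d = _validate_distance(d)
    if len(leaves) != d.shape[0]:
        raise ValidationError("leaf list does not match matrix size")
    merges = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    return Dendrogram(leaves=tuple(leaves), merges=merges, linkage=linkage)


def cophenetic_matrix(dend: Dendrogram) -> np.ndarray:
    """Ultrametric matrix: entry (i, j) is the height of the merge uniting i and j."""
    return squareform(hierarchy.cophenet(dend.merges))


def ccc(y: np.ndarray, dend: Dendrogram) -> float:
    """Cophenetic correlation coefficient between distances ``y`` and ``dend``.

    Pearson correlation over the strict upper triangles; NaN (with a warning)
    when either vector has zero variance.
    """
    y = _validate_distance(y)
    if y.shape[0] != dend.n:
        raise ValidationError("matrix size does not match dendrogram")
    iu = np.triu_indices(dend.n, k=1)
    yv = y[iu]
    zv = cophenetic_matrix(dend)[iu]
    yc = yv - yv.mean()
    zc = zv - zv.mean()
    denom = math.sqrt(float(np.sum(yc**2)) * float(np.sum(zc**2)))
    if denom == 0.0:
        warnings.warn("CCC undefined: zero variance in distances", stacklevel=2)
        return float("nan")
    return float(np.sum(yc * zc) / denom)


def z_index(d1: Dendrogram, d2: Dendrogram) -> float:
    """Normalized co-clustering disagreement between two dendrograms.

    For each cut level k = 2 .. n-1 and each leaf pair, the binary indicators
    x1, x2 say whether the pair is co-clustered in each tree; every (pair, k)
    with x1 + x2 > 0 contributes |x1 - x2| / (x1 + x2), and the mean over
    contributing terms is returned.  Pairs co-clustered in neither tree are
    skipped so that complete dissemblance can reach 1.
    """
    if set(d1.leaves) != set(d2.leaves):
        raise ValidationError("dendrograms have different leaf sets")
    if d1.n < 3:
        raise ValidationError("Z-index needs at least 3 leaves")
    order = d1.leaves
    total = 0.0
    count = 0
    for k in range(2, d1.n):
        lab1 = d1.cut(k).labels_for(order)
        lab2 = d2.cut(k).labels_for(order)
        for i, j in combinations(range(d1.n), 2):
            x1 = 1 if lab1[i] == lab1[j] else 0
            x2 = 1 if lab2[i] == lab2[j] else 0
            if x1 + x2 == 0:
                continue
            total += abs(x1 - x2) / (x1 + x2)
            count += 1
    return total / count if count else 0.0


def silhouette(p: Partition, d: np.ndarray, order: tuple[str, ...]) -> np.ndarray:
    """Per-item silhouette widths s_i = (b_i - a_i) / max(a_i, b_i).

    a_i is the mean distance to the item's own cluster (excluding itself),
    b_i the minimum over other clusters of the mean distance; singleton
    clusters get s_i = 0 by convention.
    """
    d = _validate_distance(d)
    if p.k < 2:
        raise ValidationError("silhouette requires k >= 2")
    labels = p.labels_for(order)
    n = len(order)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = int(own.sum())
        if n_own == 1:
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(
            d[i, labels == lab].mean()
            for lab in np.unique(labels)
            if lab != labels[i]
        )
        top = max(a, b)
        s[i] = 0.0 if top == 0.0 else (b - a) / top
    return s


def asw(p: Partition, d: np.ndarray, order: tuple[str, ...]) -> float:
    """Average silhouette width of a partition."""
    return float(silhouette(p, d, order).mean())


def asw_label(score: float) -> str:
    """Interpretive band for an ASW score (artificial / intermediate / structured)."""
    lo, hi = ASW_THRESHOLDS
    if score < lo:
        return "artificial"
    if score > hi:
        return "structured"
    return "intermediate"


def optimal_k(dend: Dendrogram, d: np.ndarray, k_range=None) -> tuple[int, float]:
    """Pick the cut level maximizing mean silhouette width; ties take smallest k."""
    if dend.n < 3:
        raise ValidationError("optimal_k needs at least 3 leaves")
    if k_range is None:
        k_range = range(2, dend.n)
    best_k, best_asw = None, -np.inf
    for k in sorted(k_range):
        if not 2 <= k <= dend.n - 1:
            raise ValidationError(f"k={k} outside the valid range [2, n-1]")
        p = dend.cut(k)
        score = asw(p, d, dend.leaves)
        if score > best_asw:
            best_k, best_asw = k, score
    return best_k, float(best_asw)
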