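"""Representative-term extraction from clusters of annotation terms.

Each term of the namespace carries a *bitset* of the cluster size: bit ``i``
is set iff the term is an inclusive ancestor of cluster member ``i`` (a term
is its own ancestor here, so each member's own bit is set — this is what lets
the traversal terminate at the cluster's leaves).  The bitset of a term thus
records which cluster members it summarizes.

Two bitset algorithms then operate top-down:

* **MSRT** (most specific representative terms): starting from a top term,
  descend through children whose bitset equals the top term's bitset; terms
  with no such child are emitted.  Every emitted term covers exactly the same
  cluster members as the top term but sits deeper in the DAG.
* **FCT** (find combined terms): for a representative term, look for
  combinations of ``k`` of its children whose bitset union equals the
  representative's bitset while sharing fewer than ``sct`` bits; each
  qualifying combination is refined member-wise through MSRT.  If no
  combination qualifies the representative itself is kept.

Among all candidate combinations, the one with the best (highest) mean
GO-universal IC is retained; representative terms annotating fewer than a
minimum number of gene-set genes are then discarded, the survivors being the
*synthetic terms*.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from itertools import combinations

from .annotations import AnnotationCorpus
from .errors import ValidationError
from .ic import ICTable
from .ontology import OntologyGraph


@dataclass(frozen=True)
class ClusterBitsets:
    """Ancestor-closure bitsets of one cluster, over a whole namespace.

    Bitsets are arbitrary-precision ints; bit ``i`` corresponds to
    ``cluster[i]``.  Terms unrelated to every cluster member carry 0.
    """

    cluster: tuple[str, ...]
    bits: dict[str, int]

    @property
    def full(self) -> int:
        return (1 << len(self.cluster)) - 1

    def bitset(self, term: str) -> int:
        return self.bits.get(term, 0)


def build_bitsets(cluster: list[str], g: OntologyGraph) -> ClusterBitsets:
    """Set bit i of every inclusive ancestor of cluster member i."""
    if not cluster:
        raise ValidationError("cluster must be non-empty")
    namespaces = {g.namespace(t) for t in cluster}
    if len(namespaces) != 1:
        raise ValidationError(f"cluster spans namespaces {sorted(namespaces)}")
    bits: dict[str, int] = {}
    for i, member in enumerate(cluster):
        for anc in g.ancestors(member, inclusive=True):
            bits[anc] = bits.get(anc, 0) | (1 << i)
    return ClusterBitsets(cluster=tuple(cluster), bits=bits)


def msrt(top: str, bs: ClusterBitsets, g: OntologyGraph) -> set[str]:
    """Most specific representative terms below (or equal to) ``top``.

    Breadth-first traversal; a child is followed iff its bitset equals the top
    term's bitset; a visited term with no such child is emitted.
    """
    target = bs.bitset(top)
    if target == 0:
        raise ValidationError(f"top term {top!r} has an all-zero bitset")
    to_visit: deque[str] = deque([top])
    visited: set[str] = set()
    out: set[str] = set()
    while to_visit:
        candidate = to_visit.popleft()
        if candidate in visited:
            continue
        visited.add(candidate)
        child_is_representative = False
        for child in g.children(candidate):
            if bs.bitset(child) == target:
                child_is_representative = True
                to_visit.append(child)
        if not child_is_representative:
            out.add(candidate)
    return out


def _shared_bit_count(member_bits: list[int]) -> int:
    """Number of bit positions set in at least two of the given bitsets."""
    seen = 0
    shared = 0
    for b in member_bits:
        shared |= seen & b
        seen |= b
    return bin(shared).count("1")


def fct(rep: str, k: int, sct: int, bs: ClusterBitsets, g: OntologyGraph) -> list[frozenset[str]]:
    """Find combinations of children splitting ``rep`` without losing coverage.

    k is capped at the number of children carrying a nonzero bitset (children
    unrelated to the cluster cannot contribute coverage and are skipped).  A
    combination qualifies when its bitset union equals the representative's
    bitset and its members share fewer than ``sct`` bits; each qualifying
    combination is refined member-wise through MSRT.  With no qualifying
    combination, ``[{rep}]`` is returned.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    target = bs.bitset(rep)
    children = [c for c in g.children(rep) if bs.bitset(c) != 0]
    k = min(k, len(children))
    out: list[frozenset[str]] = []
    found = False
    if k >= 1:
        for combo in combinations(children, k):
            union = 0
            for c in combo:
                union |= bs.bitset(c)
            if union != target:
                continue
            if _shared_bit_count([bs.bitset(c) for c in combo]) >= sct:
                continue
            combined: set[str] = set()
            for c in combo:
                combined |= msrt(c, bs, g)
            out.append(frozenset(combined))
            found = True
    if not found:
        out.append(frozenset({rep}))
    return out


@dataclass(frozen=True)
class RepresentativeResult:
    """Candidate representative-term sets for one cluster and the winner."""

    candidate_sets: tuple[frozenset[str], ...]
    chosen: frozenset[str]
    mean_ic: float
    tied: tuple[frozenset[str], ...] = ()


def _mean_ic(terms: frozenset[str], ic: ICTable) -> float:
    return sum(ic[t] for t in terms) / len(terms)


def select_representatives(
    cluster: list[str],
    g: OntologyGraph,
    ic_g: ICTable,
    k: int = 2,
    sct: int = 1,
    compete_parent: bool = False,
) -> RepresentativeResult:
    """Full per-cluster selection: bitsets -> MSRT from the namespace root ->
    FCT on each representative -> retain the candidate set with the best mean
    GO-universal IC (ties all reported; the first by sorted ids is primary).

    ``compete_parent=True`` additionally enters each un-split representative
    ``{rep}`` as a candidate even when combinations exist.
    """
    if not cluster:
        raise ValidationError("cluster must be non-empty")
    bs = build_bitsets(cluster, g)
    root = g.roots[g.namespace(cluster[0])]
    reps = msrt(root, bs, g)
    candidates: list[frozenset[str]] = []
    for rep in sorted(reps):
        for cand in fct(rep, k, sct, bs, g):
            if cand not in candidates:
                candidates.append(cand)
        if compete_parent and frozenset({rep}) not in candidates:
            candidates.append(frozenset({rep}))
    scored = [(_mean_ic(c, ic_g), c) for c in candidates]
    best = max(s for s, _ in scored)
    tied = sorted((c for s, c in scored if s == best), key=sorted)
    return RepresentativeResult(
        candidate_sets=tuple(candidates),
        chosen=tied[0],
        mean_ic=best,
        tied=tuple(tied),
    )


def filter_synthetic(
    reps_per_cluster: list[frozenset[str]],
    geneset: set[str],
    c: AnnotationCorpus,
    min_genes: int = 3,
) -> list[frozenset[str]]:
    """Keep representative terms annotating at least ``min_genes`` gene-set
    genes via the propagated closure; returns one (possibly empty) set per
    input cluster."""
    if min_genes < 1:
        raise ValidationError("min_genes must be >= 1")
    out: list[frozenset[str]] = []
    for reps in reps_per_cluster:
        out.append(
            frozenset(t for t in reps if len(c.genes_below(t) & geneset) >= min_genes)
        )
    return out
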