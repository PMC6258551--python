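"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's graph caches and bitset machinery:
reachability is recomputed by naive recursion over the raw edge set, bitsets
are represented as frozensets of cluster positions, and arg-max queries are
full enumerations.  They are only run on small instances.
"""

from __future__ import annotations

from itertools import combinations


def edge_map(g):
    """child -> parents adjacency straight from the raw edge triples."""
    up: dict[str, set[str]] = {t: set() for t in g.terms}
    for child, parent, _ in g.edges:
        up[child].add(parent)
    return up


def brute_ancestors(g, t):
    up = edge_map(g)
    out: set[str] = set()

    def walk(x):
        for p in up[x]:
            if p not in out:
                out.add(p)
                walk(p)

    walk(t)
    return out


def brute_descendants(g, t):
    return {u for u in g.terms if t in brute_ancestors(g, u)}


def brute_depth(g, t):
    """Longest root-to-term path by exhaustive path enumeration."""
    up = edge_map(g)

    def longest(x):
        parents = up[x]
        if not parents:
            return 0
        return 1 + max(longest(p) for p in parents)

    return longest(t)


def brute_lca(g, t1, t2):
    common = (brute_ancestors(g, t1) | {t1}) & (brute_ancestors(g, t2) | {t2})
    best = max(brute_depth(g, a) for a in common)
    return min(a for a in common if brute_depth(g, a) == best)


def brute_mica(g, ic, t1, t2):
    common = (brute_ancestors(g, t1) | {t1}) & (brute_ancestors(g, t2) | {t2})
    scored = [a for a in common if a in ic]
    best = max(ic[a] for a in scored)
    tied = [a for a in scored if ic[a] == best]
    deepest = max(brute_depth(g, a) for a in tied)
    return min(a for a in tied if brute_depth(g, a) == deepest)


def brute_bitsets(g, cluster):
    """Cluster position sets per term (frozensets, not integer masks)."""
    bits: dict[str, frozenset[int]] = {}
    for t in g.terms:
        positions = {
            i for i, m in enumerate(cluster) if t == m or t in brute_ancestors(g, m)
        }
        bits[t] = frozenset(positions)
    return bits


def brute_msrt(g, cluster, top):
    """Representative terms by full reachability enumeration: terms reachable
    from top through an all-equal-bitset chain, none of whose children carry
    the top bitset."""
    bits = brute_bitsets(g, cluster)
    target = bits[top]
    down: dict[str, set[str]] = {t: set() for t in g.terms}
    for child, parent, _ in g.edges:
        down[parent].add(child)

    reachable: set[str] = set()

    def walk(x):
        if x in reachable:
            return
        reachable.add(x)
        for c in down[x]:
            if bits[c] == target:
                walk(c)

    walk(top)
    return {t for t in reachable if not any(bits[c] == target for c in down[t])}


def brute_fct(g, cluster, rep, k, sct):
    """Qualifying child combinations by direct enumeration over position sets."""
    bits = brute_bitsets(g, cluster)
    down: dict[str, set[str]] = {t: set() for t in g.terms}
    for child, parent, _ in g.edges:
        down[parent].add(child)
    children = sorted(c for c in down[rep] if bits[c])
    k = min(k, len(children))
    out = []
    if k >= 1:
        for combo in combinations(children, k):
            union = frozenset().union(*(bits[c] for c in combo))
            if union != bits[rep]:
                continue
            shared = {
                pos
                for a, b in combinations(combo, 2)
                for pos in bits[a] & bits[b]
            }
            if len(shared) >= sct:
                continue
            merged: set[str] = set()
            for c in combo:
                merged |= brute_msrt(g, cluster, c)
            out.append(frozenset(merged))
    if not out:
        out.append(frozenset({rep}))
    return out
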