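"""Rooted DAG of ontology terms with traversal, depth, path and ancestor queries.

The ontology is modelled as a directed acyclic graph whose edges point from a
child (more specific) term to its parents, restricted to the hierarchical
relations ``is_a`` and ``part_of``.  Each namespace (sub-ontology) has exactly
one root, edges never cross namespaces, and every query that involves two
terms requires them to share a namespace.

Depth is the *longest* directed path from the namespace root to a term (the
root has depth 0); separation between two terms is the shortest up-up path
through a common ancestor.  These are the standard taxonomy conventions for
edge-based term similarity.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import CycleError, NamespaceError, NoCommonAncestorError, UnknownTermError

HIERARCHICAL_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass(frozen=True)
class TermInfo:
    name: str
    namespace: str


class OntologyGraph:
    """Immutable rooted multi-namespace DAG of terms.

    Parameters
    ----------
    terms
        Mapping from term id to ``(name, namespace)``.
    edges
        Iterable of ``(child, parent, relation)`` triples; relations must be
        hierarchical (``is_a`` / ``part_of``).
    alt_ids
        Optional mapping from secondary (alt) ids to primary ids.
    """

    def __init__(
        self,
        terms: Mapping[str, tuple[str, str]],
        edges: Iterable[tuple[str, str, str]],
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        self.terms: dict[str, TermInfo] = {
            t: TermInfo(name, ns) for t, (name, ns) in terms.items()
        }
        if not self.terms:
            raise NamespaceError("ontology has no terms")
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self._up = nx.DiGraph()  # edges child -> parent
        self._up.add_nodes_from(self.terms)
        self.edges: set[tuple[str, str, str]] = set()
        for child, parent, rel in edges:
            if rel not in HIERARCHICAL_RELATIONS:
                continue
            for t in (child, parent):
                if t not in self.terms:
                    raise UnknownTermError(t)
            if self.terms[child].namespace != self.terms[parent].namespace:
                raise NamespaceError(
                    f"edge {child}->{parent} crosses namespaces "
                    f"({self.terms[child].namespace} vs {self.terms[parent].namespace})"
                )
            self.edges.add((child, parent, rel))
            self._up.add_edge(child, parent, relation=rel)
        self._validate()
        self._depth: dict[str, int] = self._compute_depths()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self._up):
            cycle = nx.find_cycle(self._up)
            raise CycleError(f"ontology contains a cycle through {cycle[0][0]!r}")
        self.roots: dict[str, str] = {}
        by_ns: dict[str, list[str]] = {}
        for t, info in self.terms.items():
            by_ns.setdefault(info.namespace, []).append(t)
        for ns, members in by_ns.items():
            roots = sorted(t for t in members if self._up.out_degree(t) == 0)
            if len(roots) != 1:
                raise NamespaceError(
                    f"namespace {ns!r} must have exactly one root, found {roots}"
                )
            self.roots[ns] = roots[0]

    def _compute_depths(self) -> dict[str, int]:
        depth: dict[str, int] = {}
        # reverse topological order of the child->parent graph puts roots first
        for t in reversed(list(nx.topological_sort(self._up))):
            parents = list(self._up.successors(t))
            depth[t] = 0 if not parents else max(depth[p] for p in parents) + 1
        return depth

    # -- basic accessors -------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term: str) -> str | None:
        """Map an id (primary or alt) to its primary id, or None if unknown."""
        if term in self.terms:
            return term
        return self.alt_ids.get(term)

    def _check(self, term: str) -> None:
        if term not in self.terms:
            raise UnknownTermError(term)

    def namespace(self, term: str) -> str:
        self._check(term)
        return self.terms[term].namespace

    def name(self, term: str) -> str:
        self._check(term)
        return self.terms[term].name

    def namespace_terms(self, namespace: str) -> list[str]:
        if namespace not in self.roots:
            raise NamespaceError(f"unknown namespace {namespace!r}")
        return sorted(t for t, i in self.terms.items() if i.namespace == namespace)

    def parents(self, term: str) -> list[str]:
        self._check(term)
        return sorted(self._up.successors(term))

    def children(self, term: str) -> list[str]:
        self._check(term)
        return sorted(self._up.predecessors(term))

    # -- traversal queries ------------------------------------------------------

    def ancestors(self, term: str, inclusive: bool = False) -> frozenset[str]:
        """Transitive closure over child->parent edges; strict unless inclusive."""
        self._check(term)
        anc = self._ancestors_cached(term)
        return anc | {term} if inclusive else anc

    @lru_cache(maxsize=None)
    def _ancestors_cached(self, term: str) -> frozenset[str]:
        return frozenset(nx.descendants(self._up, term))

    def descendants(self, term: str, inclusive: bool = False) -> frozenset[str]:
        self._check(term)
        desc = self._descendants_cached(term)
        return desc | {term} if inclusive else desc

    @lru_cache(maxsize=None)
    def _descendants_cached(self, term: str) -> frozenset[str]:
        return frozenset(nx.ancestors(self._up, term))

    def depth(self, term: str) -> int:
        self._check(term)
        return self._depth[term]

    def max_depth(self, namespace: str) -> int:
        if namespace not in self.roots:
            raise NamespaceError(f"unknown namespace {namespace!r}")
        return max(
            self._depth[t] for t, i in self.terms.items() if i.namespace == namespace
        )

    @lru_cache(maxsize=None)
    def _up_distances(self, term: str) -> Mapping[str, int]:
        """Shortest directed (upward) edge distance from term to each inclusive ancestor."""
        dist = {term: 0}
        queue = deque([term])
        while queue:
            u = queue.popleft()
            for p in self._up.successors(u):
                if p not in dist:
                    dist[p] = dist[u] + 1
                    queue.append(p)
        return dist

    def shortest_separation(self, t1: str, t2: str) -> int:
        """Shortest up-up path length between two terms through a common ancestor."""
        self._require_same_namespace(t1, t2)
        d1, d2 = self._up_distances(t1), self._up_distances(t2)
        common = d1.keys() & d2.keys()
        if not common:
            raise NoCommonAncestorError(f"{t1} and {t2} share no ancestor")
        return min(d1[a] + d2[a] for a in common)

    def lca(self, t1: str, t2: str) -> str:
        """Lowest common ancestor: inclusive common ancestor of maximal depth.

        Ties broken by lexicographically smallest term id.
        """
        self._require_same_namespace(t1, t2)
        common = self.ancestors(t1, inclusive=True) & self.ancestors(t2, inclusive=True)
        if not common:
            raise NoCommonAncestorError(f"{t1} and {t2} share no ancestor")
        return min(common, key=lambda a: (-self._depth[a], a))

    def _require_same_namespace(self, t1: str, t2: str) -> None:
        self._check(t1)
        self._check(t2)
        ns1, ns2 = self.terms[t1].namespace, self.terms[t2].namespace
        if ns1 != ns2:
            raise NamespaceError(f"{t1} ({ns1}) and {t2} ({ns2}) are in different namespaces")


def load_obo(path, relations: Iterable[str] = ("is_a", "part_of")) -> OntologyGraph:
    """Load an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Only non-obsolete ``[Term]`` stanzas are kept; edges are restricted to the
    requested hierarchical relations.  ``alt_id`` entries are recorded so that
    annotation loaders can map secondary ids to primary ones.
    """
    relations = set(relations)
    unknown = relations - HIERARCHICAL_RELATIONS
    if unknown:
        raise ValueError(f"unsupported relations: {sorted(unknown)}")
    raw = obonet.read_obo(path, ignore_obsolete=True)
    terms: dict[str, tuple[str, str]] = {}
    alt_ids: dict[str, str] = {}
    for node, data in raw.nodes(data=True):
        name = data.get("name", node)
        namespace = data.get("namespace", "default")
        terms[node] = (name, namespace)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    edges = []
    for child, parent, rel in raw.edges(keys=True):
        if rel in relations:
            edges.append((child, parent, rel))
    return OntologyGraph(terms, edges, alt_ids=alt_ids)


def write_obo(g: OntologyGraph, path) -> None:
    """Serialize a graph to a minimal OBO 1.2 flat file (round-trips via load_obo)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: gsasynth-fixture\n")
        relationships: dict[str, list[tuple[str, str]]] = {}
        for child, parent, rel in sorted(g.edges):
            relationships.setdefault(child, []).append((rel, parent))
        for term in sorted(g.terms):
            info = g.terms[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {info.name}\n")
            fh.write(f"namespace: {info.namespace}\n")
            for rel, parent in relationships.get(term, []):
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! {g.terms[parent].name}\n")
                else:
                    fh.write(f"relationship: {rel} {parent} ! {g.terms[parent].name}\n")
        fh.write("\n[Typedef]\nid: part_of\nname: part of\n")
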