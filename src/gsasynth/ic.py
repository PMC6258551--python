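"""Information content of ontology terms.

Three IC flavours are computed, all in nats:

* **Resnik (extrinsic)** — ``IC_R(T) = -ln p(T)`` where ``p(T)`` is the
  fraction of the namespace's annotated genes that are annotated at or below
  ``T`` (after true-path propagation).  Depends on the annotation corpus.
* **Seco (intrinsic)** — ``IC_S(T) = 1 - ln(|desc(T)|+1) / ln(|desc(root)|)``
  with strict descendant counts, clamped below at 0 (the root's raw value is
  slightly negative because the denominator omits the +1).
* **GO-universal (intrinsic)** — topological probability propagation:
  ``p(root) = 1`` and ``p(x) = prod over direct parents t of p(t)/|children(t)|``;
  ``IC_GOu = -ln p``.  Zero at every namespace root, strictly increasing along
  any edge whose parent has at least two children.

The most informative common ancestor (MICA) of two terms is the inclusive
common ancestor maximizing a given IC table, with ties broken by greater depth
and then lexicographically smallest id.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Iterator

import networkx as nx

from .annotations import AnnotationCorpus
from .errors import MissingICError, NamespaceError, NoCommonAncestorError
from .ontology import OntologyGraph


@dataclass(frozen=True)
class ICTable:
    """Per-term information-content values (nats) for one IC kind."""

    kind: str  # "resnik" | "seco" | "gou"
    values: dict[str, float]

    @property
    def max_value(self) -> float:
        return max(self.values.values())

    def __getitem__(self, term: str) -> float:
        try:
            return self.values[term]
        except KeyError:
            raise MissingICError(f"no {self.kind} IC value for term {term!r}") from None

    def get(self, term: str, default=None):
        return self.values.get(term, default)

    def __contains__(self, term: str) -> bool:
        return term in self.values

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)


def ic_resnik(g: OntologyGraph, c: AnnotationCorpus, namespace: str | None = None) -> ICTable:
    """Annotation-frequency IC.  Terms with zero propagated genes get no value.

    ``p(T)`` is computed per namespace: genes annotated at/below T over all
    genes annotated anywhere in T's namespace (the root's propagated set).
    """
    if c.propagated is None:
        raise MissingICError("corpus must be propagated before computing Resnik IC")
    namespaces = [namespace] if namespace is not None else sorted(g.roots)
    values: dict[str, float] = {}
    any_genes = False
    for ns in namespaces:
        if ns not in g.roots:
            raise NamespaceError(f"unknown namespace {ns!r}")
        total = len(c.genes_below(g.roots[ns]))
        if total == 0:
            if namespace is not None:
                raise NamespaceError(f"namespace {ns!r} has no annotated genes")
            continue
        any_genes = True
        for t in g.namespace_terms(ns):
            n = len(c.genes_below(t))
            if n > 0:
                values[t] = 0.0 if n == total else -math.log(n / total)
    if not any_genes:
        raise NamespaceError("no namespace has annotated genes")
    return ICTable(kind="resnik", values=values)


def ic_seco(g: OntologyGraph) -> ICTable:
    """Descendant-count intrinsic IC, clamped below at 0."""
    values: dict[str, float] = {}
    for ns, root in sorted(g.roots.items()):
        n_root_desc = len(g.descendants(root))
        if n_root_desc < 2:
            raise NamespaceError(
                f"namespace {ns!r} is too small for Seco IC "
                f"(root has {n_root_desc} descendant(s))"
            )
        log_total = math.log(n_root_desc)
        for t in g.namespace_terms(ns):
            raw = 1.0 - math.log(len(g.descendants(t)) + 1) / log_total
            values[t] = max(0.0, raw)
    return ICTable(kind="seco", values=values)


def gou_probabilities(g: OntologyGraph) -> dict[str, float]:
    """Topological probability ``p`` of the GO-universal IC (before -ln)."""
    p: dict[str, float] = {}
    for t in reversed(list(nx.topological_sort(g._up))):  # roots first
        parents = g.parents(t)
        if not parents:
            p[t] = 1.0
        else:
            prob = 1.0
            for parent in parents:
                prob *= p[parent] / len(g.children(parent))
            p[t] = prob
    return p


def ic_gou(g: OntologyGraph) -> ICTable:
    """GO-universal intrinsic IC: ``-ln`` of the topological probability."""
    p = gou_probabilities(g)
    return ICTable(
        kind="gou", values={t: 0.0 if v == 1.0 else -math.log(v) for t, v in p.items()}
    )


def mica(g: OntologyGraph, ic: ICTable, t1: str, t2: str) -> str:
    """Most informative common ancestor under ``ic``.

    Ties broken by greater depth, then lexicographically smallest term id.
    """
    common = g.ancestors(t1, inclusive=True) & g.ancestors(t2, inclusive=True)
    if not common:
        raise NoCommonAncestorError(f"{t1} and {t2} share no ancestor")
    scored = [a for a in common if a in ic]
    if not scored:
        raise MissingICError(f"no common ancestor of {t1}, {t2} has a {ic.kind} IC value")
    return min(scored, key=lambda a: (-ic[a], -g.depth(a), a))


def write_ic_table(table: ICTable, path, checksum_inputs: dict | None = None) -> None:
    """Cache an IC table as two-column TSV plus a JSON sidecar recording the
    kind and input checksums used to invalidate the cache."""
    path = str(path)
    with open(path, "w") as fh:
        for term in sorted(table.values):
            fh.write(f"{term}\t{table.values[term]:.12g}\n")
    sidecar = {"kind": table.kind, "inputs": checksum_inputs or {}}
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, sort_keys=True)


def read_ic_table(path) -> ICTable:
    path = str(path)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    values: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            term, value = line.rstrip("\n").split("\t")
            values[term] = float(value)
    return ICTable(kind=sidecar["kind"], values=values)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
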