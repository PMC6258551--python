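"""Pairwise term semantic similarity: nine measures spanning the edge-based,
node-based (including graph-based) and hybrid families.

Edge-based measures (Ganesan, Leacock-Chodorow normalized, Pekar-Staab) use
only path lengths and depths in the DAG.  Node-based measures use term
features: Resnik-normalized, Lin and Aggregate-IC use the extrinsic
(annotation-frequency) IC; Nunivers uses the GO-universal intrinsic IC; the
Distance Function uses ancestor sets.  Zhou's measure is the hybrid, mixing a
path term with the Seco intrinsic IC.

All scores are clamped to [0, 1]; the similarity matrix forces the diagonal to
exactly 1 (Resnik-normalized and Zhou would otherwise give self-similarity
below 1, which breaks the clustering semantics of maximal self-similarity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import MissingICError, ValidationError
from .ic import ICTable, mica
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Measure:
    name: str
    category: str  # edge | node | graph | hybrid
    requires: frozenset[str]  # subset of {"ic_r", "ic_s", "ic_gou"}


#: Registry of the nine measures and the term features each one needs.
MEASURES: dict[str, Measure] = {
    m.name: m
    for m in [
        Measure("ganesan", "edge", frozenset()),
        Measure("lc", "edge", frozenset()),
        Measure("ps", "edge", frozenset()),
        Measure("zhou", "hybrid", frozenset({"ic_s"})),
        Measure("resnik", "node", frozenset({"ic_r"})),
        Measure("lin", "node", frozenset({"ic_r"})),
        Measure("nunivers", "node", frozenset({"ic_gou"})),
        Measure("df", "graph", frozenset()),
        Measure("aic", "node", frozenset({"ic_r"})),
    ]
}


def sim_ganesan(g: OntologyGraph, t1: str, t2: str) -> float:
    """Depth of the LCA against the depths of both terms."""
    if t1 == t2:
        return 1.0
    a = g.lca(t1, t2)
    return 2.0 * g.depth(a) / (g.depth(t1) + g.depth(t2))


def sim_lc(g: OntologyGraph, t1: str, t2: str) -> float:
    """Leacock-Chodorow shortest path, log-normalized by twice the maximal depth."""
    sep = g.shortest_separation(t1, t2)
    max_depth = g.max_depth(g.namespace(t1))
    denom = math.log(1 + 2 * max_depth)
    if denom == 0.0:
        return 1.0 if sep == 0 else 0.0
    return 1.0 - math.log(1 + sep) / denom


def sim_ps(g: OntologyGraph, t1: str, t2: str) -> float:
    """Pekar-Staab: root-to-LCA path against the up-paths of both terms."""
    if t1 == t2:
        return 1.0
    a = g.lca(t1, t2)
    root = g.roots[g.namespace(t1)]
    up_root = g._up_distances(a).get(root, 0)
    d1 = g._up_distances(t1)[a]
    d2 = g._up_distances(t2)[a]
    return up_root / (d1 + d2 + up_root) if (d1 + d2 + up_root) else 1.0


def sim_zhou(g: OntologyGraph, ic_s: ICTable, t1: str, t2: str, k: float = 0.5) -> float:
    """Hybrid of a normalized shortest-path term and a Seco-IC term, weight k."""
    sep = g.shortest_separation(t1, t2)
    max_depth = g.max_depth(g.namespace(t1))
    denom = math.log(2 * (max_depth - 1) + 1) if max_depth > 1 else 0.0
    path_term = (math.log(sep + 1) / denom) if denom > 0 else (0.0 if sep == 0 else 1.0)
    a = mica(g, ic_s, t1, t2)
    ic_term = (ic_s[t1] + ic_s[t2] - 2.0 * ic_s[a]) / 2.0
    return 1.0 - k * path_term - (1.0 - k) * ic_term


def sim_resnik_norm(ic_r: ICTable, g: OntologyGraph, t1: str, t2: str) -> float:
    """Resnik IC of the MICA, normalized by the maximal Resnik IC."""
    a = mica(g, ic_r, t1, t2)
    top = ic_r.max_value
    return ic_r[a] / top if top > 0 else 0.0


def sim_lin(ic_r: ICTable, g: OntologyGraph, t1: str, t2: str) -> float:
    """Lin: twice the MICA's Resnik IC over the sum of the terms' ICs."""
    if t1 == t2:
        return 1.0
    denom = ic_r[t1] + ic_r[t2]
    if denom == 0.0:
        return 0.0
    return 2.0 * ic_r[mica(g, ic_r, t1, t2)] / denom


def sim_nunivers(ic_g: ICTable, g: OntologyGraph, t1: str, t2: str) -> float:
    """Nunivers: the MICA's IC over the larger of the two terms' ICs.

    The IC family defaults to GO-universal but any table works (passing the
    Resnik table gives the "Nunivers with extrinsic IC" variant).
    """
    if t1 == t2:
        return 1.0
    denom = max(ic_g[t1], ic_g[t2])
    if denom == 0.0:
        return 0.0
    return ic_g[mica(g, ic_g, t1, t2)] / denom


def sim_df(g: OntologyGraph, t1: str, t2: str) -> float:
    """Distance Function: Jaccard index of the inclusive ancestor sets."""
    a1 = g.ancestors(t1, inclusive=True)
    a2 = g.ancestors(t2, inclusive=True)
    return len(a1 & a2) / len(a1 | a2)


def _semantic_weight(ic: float) -> float:
    """Aggregate-IC semantic weight 1/(1+exp(-1/IC)); limit 1 as IC -> 0."""
    if ic == 0.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(-1.0 / ic))


def sim_aic(ic_r: ICTable, g: OntologyGraph, t1: str, t2: str) -> float:
    """Aggregate IC: shared ancestors' semantic weights over both ancestor sums."""
    a1 = g.ancestors(t1, inclusive=True)
    a2 = g.ancestors(t2, inclusive=True)
    sw = {t: _semantic_weight(ic_r[t]) for t in a1 | a2}
    num = 2.0 * sum(sw[t] for t in a1 & a2)
    den = sum(sw[t] for t in a1) + sum(sw[t] for t in a2)
    return num / den


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise term-similarity matrix with unit diagonal."""

    terms: tuple[str, ...]
    values: np.ndarray
    measure: str

    def __post_init__(self):
        n = len(self.terms)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match term list")

    def index(self, term: str) -> int:
        return self.terms.index(term)

    def sim(self, t1: str, t2: str) -> float:
        return float(self.values[self.index(t1), self.index(t2)])

    def to_distance(self) -> np.ndarray:
        """Dissimilarity 1 - s, with an exactly zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("term\t" + "\t".join(self.terms) + "\n")
            for i, t in enumerate(self.terms):
                row = "\t".join(f"{v:.10g}" for v in self.values[i])
                fh.write(f"{t}\t{row}\n")


def pairwise_similarity(
    measure: str,
    g: OntologyGraph,
    t1: str,
    t2: str,
    *,
    ic_r: ICTable | None = None,
    ic_s: ICTable | None = None,
    ic_gou: ICTable | None = None,
    zhou_k: float = 0.5,
) -> float:
    """Evaluate one measure on one term pair (raw, before clamping)."""
    if measure == "ganesan":
        return sim_ganesan(g, t1, t2)
    if measure == "lc":
        return sim_lc(g, t1, t2)
    if measure == "ps":
        return sim_ps(g, t1, t2)
    if measure == "zhou":
        return sim_zhou(g, _need(ic_s, "ic_s", measure), t1, t2, k=zhou_k)
    if measure == "resnik":
        return sim_resnik_norm(_need(ic_r, "ic_r", measure), g, t1, t2)
    if measure == "lin":
        return sim_lin(_need(ic_r, "ic_r", measure), g, t1, t2)
    if measure == "nunivers":
        return sim_nunivers(_need(ic_gou, "ic_gou", measure), g, t1, t2)
    if measure == "df":
        return sim_df(g, t1, t2)
    if measure == "aic":
        return sim_aic(_need(ic_r, "ic_r", measure), g, t1, t2)
    raise ValidationError(f"unknown measure {measure!r}")


def _need(table: ICTable | None, name: str, measure: str) -> ICTable:
    if table is None:
        raise MissingICError(f"measure {measure!r} requires the {name} table")
    return table


def build_matrix(
    measure: str,
    terms: list[str],
    g: OntologyGraph,
    *,
    ic_r: ICTable | None = None,
    ic_s: ICTable | None = None,
    ic_gou: ICTable | None = None,
    zhou_k: float = 0.5,
) -> SimilarityMatrix:
    """Build the symmetric, clamped, unit-diagonal matrix for one measure."""
    if len(terms) < 2:
        raise ValidationError("need at least 2 terms to build a matrix")
    if len(set(terms)) != len(terms):
        raise ValidationError("term list contains duplicates")
    n = len(terms)
    values = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                raw = pairwise_similarity(
                    measure, g, terms[i], terms[j],
                    ic_r=ic_r, ic_s=ic_s, ic_gou=ic_gou, zhou_k=zhou_k,
                )
            except Exception as exc:
                raise type(exc)(
                    f"measure {measure!r} failed on pair ({terms[i]}, {terms[j]}): {exc}"
                ) from exc
            if raw < 0.0 or raw > 1.0:
                logger.debug("clamping %s(%s,%s)=%g", measure, terms[i], terms[j], raw)
            values[i, j] = values[j, i] = min(1.0, max(0.0, raw))
    return SimilarityMatrix(terms=tuple(terms), values=values, measure=measure)
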