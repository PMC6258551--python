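"""Gene-to-term annotation corpus: GAF loading, propagation, and the two
preprocessing filters (redundancy elimination, incompleteness removal).

A corpus holds the *direct* ``(gene, term, evidence)`` records and, after
:func:`propagate`, the ancestor-closed map ``term -> genes`` implied by the
true-path rule (a gene annotated to a term is implicitly annotated to every
ancestor of that term).

Filtering conventions
---------------------
* Records with evidence code ``ND`` (No biological Data available) and records
  carrying a ``NOT`` qualifier are dropped at load time.
* *Redundancy*: a direct annotation ``(gene, t)`` is redundant when the same
  gene is also directly annotated to a strict descendant of ``t``; removal
  leaves an antichain of terms per gene.
* *Incompleteness*: terms that are too generic carry little information; the
  filter drops direct annotations whose term's GO-universal IC falls below the
  first quartile of the IC distribution over the distinct terms used in the
  corpus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import NamespaceError, ParseError, ValidationError
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

#: GAF evidence code meaning "no biological data available"
ND_EVIDENCE = "ND"


@dataclass(frozen=True)
class AnnotationCorpus:
    """Immutable set of direct gene->term annotations plus propagated closure."""

    direct: frozenset[tuple[str, str, str]]  # (gene, term, evidence)
    propagated: dict[str, frozenset[str]] | None = field(default=None, compare=False)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _, _ in self.direct)

    @property
    def direct_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((g, t) for g, t, _ in self.direct)

    def direct_terms(self) -> frozenset[str]:
        """Distinct terms used in direct annotations."""
        return frozenset(t for _, t, _ in self.direct)

    def terms_of(self, gene: str) -> frozenset[str]:
        return frozenset(t for g, t, _ in self.direct if g == gene)

    def genes_below(self, term: str) -> frozenset[str]:
        """Genes annotated (after propagation) at or below ``term``."""
        if self.propagated is None:
            raise ValidationError("corpus is not propagated; call propagate() first")
        return self.propagated.get(term, frozenset())


def load_gaf(path, g: OntologyGraph) -> AnnotationCorpus:
    """Load a GAF 2.x file against an ontology.

    Column 3 (DB Object Symbol) is the gene, column 5 the GO id, column 4 the
    qualifier, column 7 the evidence code.  ``ND``-evidence and ``NOT``-qualified
    rows are dropped; ids are resolved through ``alt_id``; rows whose term is
    absent from the ontology are dropped with a warning.
    """
    records: set[tuple[str, str, str]] = set()
    n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise ParseError(f"{path}:{lineno}: expected >=15 GAF columns, got {len(cols)}")
            symbol, qualifier, go_id, evidence = cols[2], cols[3], cols[4], cols[6]
            if not symbol or not go_id:
                raise ParseError(f"{path}:{lineno}: empty gene symbol or GO id")
            if evidence == ND_EVIDENCE:
                continue
            if "NOT" in qualifier.split("|"):
                continue
            primary = g.resolve(go_id)
            if primary is None:
                n_unknown += 1
                continue
            records.add((symbol, primary, evidence))
    if n_unknown:
        logger.warning("dropped %d annotation rows with terms absent from the ontology", n_unknown)
    if not records:
        raise ValidationError(f"no usable annotation records in {path}")
    return AnnotationCorpus(direct=frozenset(records))


def propagate(c: AnnotationCorpus, g: OntologyGraph) -> AnnotationCorpus:
    """Ancestor-close the corpus: ``propagated(t)`` is the union of genes
    directly annotated to any term whose inclusive ancestors contain ``t``."""
    prop: dict[str, set[str]] = {}
    for gene, term, _ in c.direct:
        for anc in g.ancestors(term, inclusive=True):
            prop.setdefault(anc, set()).add(gene)
    frozen = {t: frozenset(genes) for t, genes in prop.items()}
    return replace(c, propagated=frozen)


def remove_redundant(c: AnnotationCorpus, g: OntologyGraph) -> AnnotationCorpus:
    """Drop a direct annotation when a strict descendant of its term annotates
    the same gene; per gene the surviving terms form an antichain."""
    by_gene: dict[str, set[str]] = {}
    for gene, term, _ in c.direct:
        by_gene.setdefault(gene, set()).add(term)
    keep: set[tuple[str, str, str]] = set()
    for gene, term, ev in c.direct:
        others = by_gene[gene]
        if g.descendants(term) & others:
            continue
        keep.add((gene, term, ev))
    return AnnotationCorpus(direct=frozenset(keep))


def remove_incomplete(c: AnnotationCorpus, ic_gou) -> AnnotationCorpus:
    """Drop direct annotations whose term's GO-universal IC lies strictly below
    the first quartile of the distinct-term IC distribution of the corpus.

    With fewer than four distinct annotated terms the quartile is meaningless
    and the corpus is returned unchanged (with a warning).
    """
    terms = sorted(c.direct_terms())
    if len(terms) < 4:
        logger.warning("fewer than 4 distinct terms; incompleteness filter skipped")
        return c
    values = np.array([ic_gou[t] for t in terms], dtype=float)
    q1 = float(np.quantile(values, 0.25))
    keep = frozenset(rec for rec in c.direct if ic_gou[rec[1]] >= q1)
    if not keep:
        raise ValidationError("incompleteness filter removed every annotation")
    return AnnotationCorpus(direct=keep)


def restrict_namespace(c: AnnotationCorpus, g: OntologyGraph, namespace: str) -> AnnotationCorpus:
    """Keep only direct annotations whose term belongs to ``namespace``."""
    if namespace not in g.roots:
        raise NamespaceError(f"unknown namespace {namespace!r}")
    keep = frozenset(rec for rec in c.direct if g.namespace(rec[1]) == namespace)
    if not keep:
        logger.warning("no annotations in namespace %r", namespace)
    return AnnotationCorpus(direct=keep)
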