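"""Deterministic generators of GO-like fixtures.

Everything the pipeline consumes can be generated here without downloads: a
rooted multi-parent DAG with is_a/part_of edges, a gene-annotation corpus with
the strongly right-skewed term usage real annotation corpora show (a small
fraction of popular terms carries most annotations), planted-block similarity
matrices for exercising the clustering diagnostics, and the small hand-checked
``toy5`` ontology used throughout the test suite.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationCorpus, propagate
from .errors import ValidationError
from .ontology import OntologyGraph
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the random DAG / corpus generators."""

    n_terms: int = 50
    max_parents: int = 2
    n_genes: int = 100
    annotations_per_gene: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 2:
            raise ValidationError("n_terms must be >= 2")
        if self.max_parents < 1:
            raise ValidationError("max_parents must be >= 1")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")


def toy5() -> tuple[OntologyGraph, AnnotationCorpus]:
    """Canonical 6-term fixture: root R with children A, B; A has leaves C, D;
    B has leaf E.  Four genes annotated to C, D, E and A (one each)."""
    terms = {t: (f"term {t}", "synthetic") for t in "RABCDE"}
    edges = [
        ("A", "R", "is_a"),
        ("B", "R", "is_a"),
        ("C", "A", "is_a"),
        ("D", "A", "is_a"),
        ("E", "B", "is_a"),
    ]
    g = OntologyGraph(terms, edges)
    direct = frozenset(
        [("g1", "C", "EXP"), ("g2", "D", "EXP"), ("g3", "E", "EXP"), ("g4", "A", "EXP")]
    )
    corpus = propagate(AnnotationCorpus(direct=direct), g)
    return g, corpus


def random_dag(spec: FixtureSpec, namespace: str = "synthetic") -> OntologyGraph:
    """Single-root random DAG: term i >= 1 draws 1..max_parents distinct
    parents uniformly among terms 0..i-1 (term 0 is the root); roughly one
    edge in five is a part_of relation."""
    rng = np.random.default_rng(spec.seed)
    ids = [f"SYN:{i:07d}" for i in range(spec.n_terms)]
    terms = {t: (f"synthetic term {i}", namespace) for i, t in enumerate(ids)}
    edges = []
    for i in range(1, spec.n_terms):
        n_par = int(rng.integers(1, min(spec.max_parents, i) + 1))
        parents = rng.choice(i, size=n_par, replace=False)
        for p in sorted(int(x) for x in parents):
            rel = "part_of" if rng.random() < 0.2 else "is_a"
            edges.append((ids[i], ids[p], rel))
    return OntologyGraph(terms, edges)


def random_corpus(g: OntologyGraph, spec: FixtureSpec) -> AnnotationCorpus:
    """Zipf-skewed random corpus: term popularity is proportional to 1/rank
    over a seed-fixed random term order, so a small share of terms carries
    most annotations; each gene draws at least one term."""
    rng = np.random.default_rng(spec.seed + 1)
    terms = sorted(g.terms)
    order = rng.permutation(len(terms))
    weights = 1.0 / (1.0 + np.argsort(order))
    probs = weights / weights.sum()
    direct: set[tuple[str, str, str]] = set()
    for j in range(spec.n_genes):
        gene = f"g{j + 1:04d}"
        n_ann = max(1, int(rng.poisson(spec.annotations_per_gene)))
        n_ann = min(n_ann, len(terms))
        chosen = rng.choice(len(terms), size=n_ann, replace=False, p=probs)
        for idx in sorted(int(x) for x in chosen):
            direct.add((gene, terms[idx], "IEA"))
    return AnnotationCorpus(direct=frozenset(direct))


def planted_similarity(
    k_blocks: int,
    block_size: int,
    within: float,
    between: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SimilarityMatrix:
    """Block-constant similarity matrix with optional Gaussian noise.

    Items in the same block have similarity ``within``, across blocks
    ``between``; symmetric noise of standard deviation ``noise_sd`` is added
    to the off-diagonal entries, then everything is clamped to [0, 1] and the
    diagonal forced to 1.
    """
    if k_blocks < 1 or block_size < 1:
        raise ValidationError("k_blocks and block_size must be >= 1")
    n = k_blocks * block_size
    labels = np.repeat(np.arange(k_blocks), block_size)
    values = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        noise = np.triu(noise, k=1)
        values = values + noise + noise.T
    values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    items = tuple(f"item{i + 1:04d}" for i in range(n))
    return SimilarityMatrix(terms=items, values=values, measure="planted")


def random_genesets(
    c: AnnotationCorpus, n_sets: int, genes_per_set: int, seed: int = 0
) -> dict[str, list[str]]:
    """Sample gene sets (without replacement per set) from a corpus' genes."""
    rng = np.random.default_rng(seed + 2)
    genes = sorted(c.genes)
    size = min(genes_per_set, len(genes))
    out: dict[str, list[str]] = {}
    for s in range(n_sets):
        chosen = rng.choice(len(genes), size=size, replace=False)
        out[f"set{s + 1:02d}"] = sorted(genes[int(i)] for i in chosen)
    return out


def write_gaf(c: AnnotationCorpus, path) -> None:
    """Serialize direct annotations as a minimal GAF 2.2 file."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene, term, evidence in sorted(c.direct):
            cols = [
                "SYNDB", gene, gene, "involved_in", term, "SYN_REF:0000001",
                evidence, "", "P", "", "", "protein", "taxon:0000", "20180101",
                "SYNDB", "", "",
            ]
            fh.write("\t".join(cols) + "\n")


def write_gmt(genesets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(genesets):
            fh.write("\t".join([name, "synthetic gene set", *genesets[name]]) + "\n")
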