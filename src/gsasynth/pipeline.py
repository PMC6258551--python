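"""End-to-end orchestration: preprocess annotations, build per-gene-set
similarity matrices, cluster, extract representative/synthetic terms, and
emit the synthesis/coverage reports.

The workflow per gene set and measure is: namespace restriction ->
redundancy elimination -> incompleteness removal -> the gene set's term
universe -> similarity matrix -> distance -> agglomeration -> CCC ->
optimal-K cut -> representative terms per cluster -> synthetic-term filter ->
IC-quartile synthesis and coverage percentages.

All outputs (reports, manifest) are written deterministically: rows and keys
are sorted, floats fixed-format, no timestamps, so a re-run on identical
inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import annotations as ann
from . import cluster as cl
from . import ic as icmod
from . import representatives as rep
from . import report as rp
from . import similarity as sim
from .errors import GsaError, ParseError, ValidationError
from .ontology import OntologyGraph, load_obo

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass(frozen=True)
class PipelineConfig:
    obo: str
    gaf: str
    genesets: str
    out_dir: str
    namespace: str = "biological_process"
    relations: tuple[str, ...] = ("is_a", "part_of")
    measures: tuple[str, ...] = tuple(sorted(sim.MEASURES))
    linkage: str = "average"
    min_genes: int = 3
    fct_k: int = 2
    fct_sct: int = 1
    zhou_k: float = 0.5
    incompleteness_filter: bool = True
    compete_parent: bool = False
    min_terms: int = 3  # gene sets with fewer annotated terms are skipped
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.measures) - set(sim.MEASURES)
        if unknown:
            raise ValidationError(f"unknown measures: {sorted(unknown)}")
        if self.linkage not in cl.LINKAGES:
            raise ValidationError(f"unknown linkage {self.linkage!r}")


def load_genesets(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (>= 3 tab-separated columns) or two-column TSV
    (set id, gene; one gene per row)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise ParseError(f"no gene sets in {path}")
    if path.suffix.lower() == ".gmt" or all(len(r) >= 3 for r in rows):
        for lineno, r in enumerate(rows, start=1):
            if len(r) < 3:
                raise ParseError(f"{path}:{lineno}: GMT rows need >= 3 columns")
            sets[r[0]] = sorted(set(g for g in r[2:] if g))
    else:
        for lineno, r in enumerate(rows, start=1):
            if len(r) != 2:
                raise ParseError(f"{path}:{lineno}: two-column TSV expected")
            sets.setdefault(r[0], []).append(r[1])
        sets = {k: sorted(set(v)) for k, v in sets.items()}
    return sets


@dataclass
class _Prepared:
    """Shared preprocessing state reused across measures and gene sets."""

    graph: OntologyGraph
    corpus: ann.AnnotationCorpus  # preprocessed + propagated
    ic_r: icmod.ICTable
    ic_s: icmod.ICTable
    ic_g: icmod.ICTable
    bounds: rp.QuartileBounds
    genesets: dict[str, list[str]]


def _prepare(cfg: PipelineConfig) -> _Prepared:
    graph = load_obo(cfg.obo, relations=cfg.relations)
    corpus = ann.load_gaf(cfg.gaf, graph)
    corpus = ann.restrict_namespace(corpus, graph, cfg.namespace)
    if not corpus.direct:
        raise ValidationError(f"no annotations in namespace {cfg.namespace!r}")
    ic_g = icmod.ic_gou(graph)
    corpus = ann.remove_redundant(corpus, graph)
    if cfg.incompleteness_filter:
        corpus = ann.remove_incomplete(corpus, ic_g)
    corpus = ann.propagate(corpus, graph)
    ic_r = icmod.ic_resnik(graph, corpus, namespace=cfg.namespace)
    ic_s = icmod.ic_seco(graph)
    bounds = rp.ic_quartiles(corpus, ic_g)
    genesets = load_genesets(cfg.genesets)
    return _Prepared(graph, corpus, ic_r, ic_s, ic_g, bounds, genesets)


def _term_universe(prep: _Prepared, genes: set[str]) -> list[str]:
    """Distinct (post-preprocessing) direct terms annotating the gene set."""
    return sorted({t for g, t, _ in prep.corpus.direct if g in genes})


def _dendrogram(prep: _Prepared, cfg: PipelineConfig, measure: str, terms: list[str], linkage: str):
    matrix = sim.build_matrix(
        measure, terms, prep.graph,
        ic_r=prep.ic_r, ic_s=prep.ic_s, ic_gou=prep.ic_g, zhou_k=cfg.zhou_k,
    )
    d = matrix.to_distance()
    return d, cl.agglomerate(d, terms, linkage)


def _analyze_one(
    prep: _Prepared, cfg: PipelineConfig, set_id: str, measure: str
) -> rp.SynthesisReport | None:
    genes = set(prep.genesets[set_id])
    terms = _term_universe(prep, genes)
    if len(terms) < cfg.min_terms:
        logger.info("skipping %s/%s: only %d annotated terms", set_id, measure, len(terms))
        return None
    d, dend = _dendrogram(prep, cfg, measure, terms, cfg.linkage)
    ccc_score = cl.ccc(d, dend)
    k, asw_score = cl.optimal_k(dend, d)
    partition = dend.cut(k)
    clusters: dict[int, list[str]] = {}
    for t in terms:
        clusters.setdefault(partition.assignment[t], []).append(t)
    reps_per_cluster = []
    for label in sorted(clusters):
        result = rep.select_representatives(
            clusters[label], prep.graph, prep.ic_g,
            k=cfg.fct_k, sct=cfg.fct_sct, compete_parent=cfg.compete_parent,
        )
        reps_per_cluster.append(result.chosen)
    synthetic_sets = rep.filter_synthetic(
        reps_per_cluster, genes, prep.corpus, min_genes=cfg.min_genes
    )
    representative = sorted(set().union(*reps_per_cluster))
    synthetic = sorted(set().union(*synthetic_sets)) if synthetic_sets else []
    term_pct = rp.cumulative_synthesis(set(synthetic), prep.bounds, prep.ic_g, len(terms))
    gene_pct = rp.cumulative_coverage(set(synthetic), genes, prep.corpus, prep.bounds, prep.ic_g)
    report = rp.SynthesisReport(
        gene_set_id=set_id,
        measure=measure,
        linkage=cfg.linkage,
        n_genes=len(genes),
        n_original_terms=len(terms),
        n_representative_terms=len(representative),
        n_synthetic_terms=len(synthetic),
        ccc=ccc_score,
        asw=asw_score,
        optimal_k=k,
        term_pct=term_pct,
        gene_pct=gene_pct,
    )
    report.validate()
    return report


def run_pipeline(cfg: PipelineConfig) -> list[rp.SynthesisReport]:
    """Run the full workflow and write report TSV/JSON plus a run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prep = _prepare(cfg)
    reports: list[rp.SynthesisReport] = []
    for set_id in sorted(prep.genesets):
        for measure in cfg.measures:
            try:
                r = _analyze_one(prep, cfg, set_id, measure)
            except GsaError as exc:
                logger.error("gene set %s, measure %s failed: %s", set_id, measure, exc)
                continue
            if r is not None:
                reports.append(r)
    rp.write_reports_tsv(reports, out / "reports.tsv")
    with open(out / "reports.json", "w") as fh:
        json.dump([r.as_dict() for r in reports], fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest = {
        "config": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in vars(cfg).items()
            if k != "out_dir"  # not an input; keeps re-runs byte-comparable
        },
        "inputs": {
            "obo_sha256": icmod.file_checksum(cfg.obo),
            "gaf_sha256": icmod.file_checksum(cfg.gaf),
            "genesets_sha256": icmod.file_checksum(cfg.genesets),
        },
        "version": __version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return reports


def compare_linkages(
    cfg: PipelineConfig, linkages: tuple[str, str] = ("complete", "average")
) -> list[dict]:
    """Z-index between the dendrograms of two linkage methods, per gene set
    and measure."""
    if len(linkages) != 2:
        raise ValidationError("exactly two linkages required")
    for lk in linkages:
        if lk not in cl.LINKAGES:
            raise ValidationError(f"unknown linkage {lk!r}")
    prep = _prepare(cfg)
    rows: list[dict] = []
    for set_id in sorted(prep.genesets):
        genes = set(prep.genesets[set_id])
        terms = _term_universe(prep, genes)
        if len(terms) < max(cfg.min_terms, 3):
            continue
        for measure in cfg.measures:
            try:
                _, d1 = _dendrogram(prep, cfg, measure, terms, linkages[0])
                _, d2 = _dendrogram(prep, cfg, measure, terms, linkages[1])
                z = cl.z_index(d1, d2)
            except GsaError as exc:
                logger.error("gene set %s, measure %s failed: %s", set_id, measure, exc)
                continue
            rows.append(
                {
                    "gene_set_id": set_id,
                    "measure": measure,
                    "linkage_a": linkages[0],
                    "linkage_b": linkages[1],
                    "z_index": round(z, 6),
                }
            )
    return rows
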