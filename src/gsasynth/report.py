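"""Synthesis/coverage evaluation of synthetic terms by GO-universal IC quartile.

The reference corpus' distinct annotated terms define a GO-universal IC
distribution; its quartile boundaries split the IC range into four intervals
of equal term density.  For a gene set the report gives, cumulatively from the
most specific side (right-to-left):

* ``term_pct`` Q0..Q3 — percentage of the gene set's original (post-filter)
  terms that survive as synthetic terms with IC at least the quartile bound
  (Q0 has no bound, so it is the overall synthesis rate);
* ``gene_pct`` Q0..Q3 — percentage of the gene set's genes still covered via
  propagated annotation by at least one such synthetic term.

Both vectors are non-increasing from Q0 to Q3 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationCorpus
from .errors import ValidationError
from .ic import ICTable


@dataclass(frozen=True)
class QuartileBounds:
    q1: float
    q2: float
    q3: float

    def __post_init__(self):
        if not (self.q1 <= self.q2 <= self.q3):
            raise ValidationError("quartile bounds must be non-decreasing")


def ic_quartiles(c: AnnotationCorpus, ic_g: ICTable) -> QuartileBounds:
    """Quartile boundaries of the distinct-annotated-term IC distribution
    (linear-interpolation quantiles)."""
    terms = sorted(c.direct_terms())
    if len(terms) < 4:
        raise ValidationError("need at least 4 distinct annotated terms for quartiles")
    values = np.array([ic_g[t] for t in terms], dtype=float)
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return QuartileBounds(q1=float(q1), q2=float(q2), q3=float(q3))


def cumulative_synthesis(
    synthetic: set[str], bounds: QuartileBounds, ic_g: ICTable, n_original: int
) -> tuple[float, float, float, float]:
    """Right-to-left cumulative percentages of synthetic terms per quartile,
    relative to the gene set's original term count."""
    if n_original <= 0:
        raise ValidationError("n_original must be positive")
    cuts = (-np.inf, bounds.q1, bounds.q2, bounds.q3)
    return tuple(
        100.0 * sum(1 for t in synthetic if ic_g[t] >= cut) / n_original for cut in cuts
    )


def cumulative_coverage(
    synthetic: set[str],
    geneset: set[str],
    c: AnnotationCorpus,
    bounds: QuartileBounds,
    ic_g: ICTable,
) -> tuple[float, float, float, float]:
    """Percentage of gene-set genes covered by at least one synthetic term of
    IC at least each cumulative quartile bound."""
    if not geneset:
        raise ValidationError("geneset must be non-empty")
    cuts = (-np.inf, bounds.q1, bounds.q2, bounds.q3)
    out = []
    for cut in cuts:
        covered: set[str] = set()
        for t in synthetic:
            if ic_g[t] >= cut:
                covered |= c.genes_below(t) & geneset
        out.append(100.0 * len(covered) / len(geneset))
    return tuple(out)


@dataclass(frozen=True)
class SynthesisReport:
    """One row of the evaluation: a gene set under one measure and linkage."""

    gene_set_id: str
    measure: str
    linkage: str
    n_genes: int
    n_original_terms: int
    n_representative_terms: int
    n_synthetic_terms: int
    ccc: float
    asw: float
    optimal_k: int
    term_pct: tuple[float, float, float, float]
    gene_pct: tuple[float, float, float, float]

    TSV_COLUMNS = (
        "gene_set_id", "measure", "linkage", "n_genes", "n_original_terms",
        "n_representative_terms", "n_synthetic_terms", "ccc", "asw", "optimal_k",
        "term_pct_q0", "term_pct_q1", "term_pct_q2", "term_pct_q3",
        "gene_pct_q0", "gene_pct_q1", "gene_pct_q2", "gene_pct_q3",
    )

    def validate(self) -> None:
        for vec in (self.term_pct, self.gene_pct):
            if any(vec[i] < vec[i + 1] - 1e-9 for i in range(3)):
                raise ValidationError("cumulative percentages must be non-increasing")

    def as_row(self) -> list[str]:
        return [
            self.gene_set_id, self.measure, self.linkage, str(self.n_genes),
            str(self.n_original_terms), str(self.n_representative_terms),
            str(self.n_synthetic_terms), f"{self.ccc:.6f}", f"{self.asw:.6f}",
            str(self.optimal_k),
            *(f"{v:.4f}" for v in self.term_pct),
            *(f"{v:.4f}" for v in self.gene_pct),
        ]

    def as_dict(self) -> dict:
        return dict(zip(self.TSV_COLUMNS, self.as_row()))


def write_reports_tsv(reports: list[SynthesisReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SynthesisReport.TSV_COLUMNS) + "\n")
        for r in reports:
            fh.write("\t".join(r.as_row()) + "\n")
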