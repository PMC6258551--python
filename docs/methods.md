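# Methods

This note documents the models and procedures implemented in `gsasynth`, the
conventions adopted where the underlying definitions leave room, and what the
synthetic fixtures do and do not emulate.

## Ontology model

The ontology is a rooted DAG per namespace, with child→parent edges restricted
to the hierarchical relations `is_a` and `part_of`. Transversal relations
(`regulates`, …) are excluded: the term hierarchy the pipeline summarizes is
the subsumption hierarchy, and paths through transversal edges would not be
specificity-ordered. `part_of` is traversed by default because it is
hierarchical in the same sense; `load_obo(relations={"is_a"})` (CLI
`--relations is_a`) gives the is_a-only reading.

Conventions:

* **depth(t)** — edge count of the *longest* root→t path; root depth 0.
* **ancestors / descendants** — strict transitive closures unless the
  `inclusive` flag is set; every consumer states which it uses.
* **separation(t1, t2)** — minimum over common ancestors a of the shortest
  upward distances t1→a plus t2→a. Paths are constrained to run up–up through
  a common ancestor (standard taxonomy convention; routes down through
  unrelated descendants are meaningless for specificity).
* **LCA** — inclusive common ancestor of maximal depth, ties broken by
  lexicographically smallest id (determinism across platforms).
* Cross-namespace queries raise an error rather than returning 0; namespaces
  are analyzed independently.

## Annotation corpus

GAF 2.x records are reduced to (gene symbol, term, evidence code); rows with
the `NOT` qualifier or the `ND` evidence code are dropped, all other evidence
codes are kept. Propagation applies the true-path rule: a gene annotated to a
term is annotated to all of its ancestors. Two filters precede any analysis:

* **Redundancy** — per gene, a direct annotation is removed when a strict
  descendant of its term annotates the same gene; the result is an antichain
  per gene and the operation is idempotent.
* **Incompleteness** — terms that are too generic are removed: the
  GO-universal IC of each *distinct* term used in the corpus forms a
  distribution, and direct annotations whose term IC is strictly below the
  first quartile are dropped. Quartiles use linear interpolation between
  order statistics (position (n−1)·q, NumPy's default), and boundary terms
  are retained (strict `<`); with fewer than four distinct terms the filter
  is a no-op. The quartile population is distinct terms, not annotation
  occurrences, and is computed corpus-wide, mirroring a reference corpus such
  as a whole-species annotation file rather than a single gene set.

Filter order in the pipeline: namespace restriction → redundancy →
incompleteness. The default namespace is `biological_process`, where the most
specific functional descriptions live.

## Information content

All ICs are in nats (natural log throughout, so IC ratios are base-invariant):

* **Extrinsic (Resnik)** — IC_R(T) = −ln p(T), p(T) = genes annotated at or
  below T over all genes annotated in T's namespace. The denominator is a
  gene count, not an annotation-row count; the two readings differ by a
  constant shift which cancels in Lin but not in Resnik-normalized, and the
  gene-count reading is the standard one. Terms with zero annotated genes
  carry no value; a similarity request touching them is an error, not an
  imputation.
* **Intrinsic (Seco)** — IC_S(T) = 1 − ln(|desc(T)|+1)/ln(|desc(root)|) with
  strict descendant counts, clamped below at 0 (as written the root's value
  is slightly negative since the denominator lacks the +1). Namespaces with
  fewer than two root descendants make the denominator degenerate and are
  rejected.
* **Intrinsic (GO-universal)** — topological probability propagation:
  p(root) = 1, p(x) = ∏ over direct parents t of p(t)/|children(t)|,
  IC = −ln p. "Parents" and "children" are direct, not transitive: the
  transitive reading would collapse p super-exponentially and lose the
  measure's meaning as a branching-aware specificity. On a pure chain the IC
  is identically 0 — specificity here is *earned by branching*, a documented
  degenerate case.
* **MICA** — inclusive common ancestor maximizing the given IC table, ties
  broken by greater depth then lexicographic id. MICA is recomputed per IC
  family (Zhou uses the Seco MICA, Resnik/Lin the extrinsic one, Nunivers the
  GO-universal one).

## The nine similarity measures

The measure set spans three families — edge-based (Ganesan, LC, PS),
node-based (Resnik-normalized, Lin, Nunivers, DF, AIC) and hybrid (Zhou).
The exact functional forms implemented:

| measure | score for (t1, t2) |
|---|---|
| ganesan | 2·depth(lca) / (depth(t1)+depth(t2)); 1 when t1 = t2 |
| lc | 1 − ln(1+sep) / ln(1+2·max_depth) |
| ps | sep(root,a) / (sep(t1,a)+sep(t2,a)+sep(root,a)), a = lca; 1 when t1 = t2 |
| zhou | 1 − k·ln(sep+1)/ln(2(max_depth−1)+1) − (1−k)·(IC_S(t1)+IC_S(t2)−2·IC_S(mica))/2, k = 0.5 |
| resnik | IC_R(mica) / max IC_R |
| lin | 2·IC_R(mica) / (IC_R(t1)+IC_R(t2)) |
| nunivers | IC_GOu(mica) / max(IC_GOu(t1), IC_GOu(t2)) |
| df | Jaccard of inclusive ancestor sets |
| aic | Σ_shared 2·SW / (Σ_A1 SW + Σ_A2 SW), SW(t) = 1/(1+e^(−1/IC_R(t))), SW = 1 at IC 0 |

Conventions: LC's normalization (log ratio with +1 offsets against twice the
maximal depth) and PS's identity value are this package's pinned choices —
the literature states the ingredients of these measures more often than a
single normalized form, and pinning one exact formula is what makes results
comparable across measures. DF is implemented as the inclusive-ancestor
Jaccard index, the natural set-based reading of "similarity from the
ancestors of the two terms". Zhou's mixing weight defaults to k = 0.5, the
value its authors suggest. All scores are clamped to [0, 1] after evaluation
(clamps logged at debug level), and the matrix diagonal is forced to exactly
1 — Resnik-normalized and Zhou would otherwise score self-similarity below 1,
which breaks the "maximal self-similarity" premise of clustering on 1 − s.
"Nunivers with extrinsic IC" is available by passing the Resnik table to
`sim_nunivers`, but is not one of the nine defaults.

## Clustering and diagnostics

Distance is 1 − similarity. Agglomeration (single, complete, average linkage)
delegates to `scipy.cluster.hierarchy.linkage`, whose nearest-neighbor-chain
algorithm is deterministic for a given input matrix; ties in merge order are
resolved by scipy's scan order, reproducibly across runs and platforms.
Single linkage is implemented and tested but excluded from the default
pipeline (it chains on hierarchical data); average linkage is the default.

* **CCC** is the Pearson correlation between the strict upper triangles of
  the input distances and the cophenetic matrix (merge height of the first
  cluster uniting each pair). It is implemented exactly as a correlation, not
  its square; zero variance on either side returns NaN with a warning.
* **Z-index** compares two dendrograms over all non-trivial cut levels
  k = 2 … n−1. Cutting applies the first n−k merges in agglomeration order,
  which always yields exactly k clusters even under tied heights. For every
  (pair, k) the indicators x1, x2 ∈ {0,1} mark co-clustering in each tree;
  terms with x1 + x2 = 0 are skipped (counting them as agreement would make
  the dissemblance extreme 1 unreachable) and |x1 − x2|/(x1 + x2) is averaged
  over the rest, giving 0 for identical trees and 1 for fully crossed
  nestings.
* **Silhouette** uses the standard a/b form with s = 0 for singleton
  clusters; **ASW** is its mean, and the optimal K is the argmax of ASW over
  cuts (ties to the smallest K). The 0.25/0.50 interpretive bands are
  reported as labels only, never used to gate computation.

## Representative and synthetic terms

Bitsets are arbitrary-precision integers over cluster positions; bit i of
term t is set iff t is an *inclusive* ancestor of cluster member i. The
self-ancestor convention is required for the traversal to terminate at the
cluster's own leaves. MSRT compares children against the bitset of the *top*
term (not the current candidate's): descend while a child preserves the top
bitset, emit terms where no child does. FCT examines k-combinations of a
representative's children whose bitset union equals the representative's and
whose members share fewer than sct bit positions, refining each member
through MSRT; children with an all-zero bitset are not combination candidates
(they contribute no coverage, and MSRT is undefined on them). FCT is applied
once per MSRT output, without recursion into its own results.

Defaults: k = 2 (the smallest non-trivial split), sct = 1 (members must be
bit-disjoint). The un-split representative competes against found
combinations only when `compete_parent` is set; by default it appears only as
the fallback when no combination qualifies. Combination quality is the mean
GO-universal IC of its terms — the same specificity currency used by the
incompleteness filter and the quartile report — and ties are all reported
with the lexicographically first set marked primary. Representative terms
annotating fewer than `min_genes = 3` genes of the gene set (via the
propagated closure) are dropped; the survivors are the synthetic terms.

## Evaluation report

The reference corpus' distinct-term GO-universal IC distribution is split at
its quartiles (linear interpolation). For each gene set × measure the report
gives cumulative percentages from the specific side: the Qj term percentage
counts synthetic terms with IC ≥ bound_j over the gene set's
post-preprocessing term count (bound_0 = −∞, so Q0 is the synthesis rate);
the Qj gene percentage counts gene-set genes covered by at least one such
term. Boundary handling is ≥ (a term exactly on a quartile bound counts in
that quartile). Coverage denominators include all gene-set genes, annotated
or not — an unannotated gene is genuinely uncovered.

## Synthetic fixtures

The generators exist so the whole pipeline is testable without downloads:

* `random_dag` — single-root DAG; term i draws 1 … max_parents parents
  uniformly among earlier terms; ~20% of edges are `part_of`.
* `random_corpus` — term popularity ∝ 1/rank over a seed-fixed random order
  (Zipf-like), Poisson(3) annotations per gene with a minimum of one. At the
  default sizes (50 terms, 100 genes) the top fifth of terms carries over
  half of the annotations, emulating the strong usage skew of real annotation
  corpora. Defaults were sized so this skew is stable; sampling without
  replacement flattens the skew on very small ontologies.
* `planted_similarity` — block-constant similarity plus truncated symmetric
  Gaussian noise, the test bed for the clustering diagnostics.

What the fixtures do **not** emulate: evidence-code composition, obsolete
term churn, the depth profile of real GO namespaces, and any biological
correlation between gene sets and ontology structure. Tests passing on these
fixtures validate the algorithmic contracts (closure, monotonicity, oracle
equality, determinism), not biological conclusions about real gene sets.

Pipeline-level tests use a 20-term DAG with 30 genes and 2–3 gene sets, and
the diagnostics tests use planted matrices of 6–16 items — sizes at which the
brute-force oracles remain exhaustive; all stages are linear-to-cubic in the
term count and run identically at realistic sizes.

## Numerical and degenerate-input policy

* Quantiles: linear interpolation everywhere (annotation filter, report).
* Similarity 0/0 cases are pinned per measure (identity → 1; distinct terms
  with all-zero IC → 0).
* Gene sets with fewer than 3 annotated terms are skipped with a logged
  reason; an empty corpus after filtering is a validation error.
* All randomness flows through explicit integer seeds; no wall-clock
  defaults. Pipeline outputs are sorted and fixed-format so re-runs are
  byte-identical.

## Known limitations

* No OWL parsing, no transversal relations, no groupwise (gene-level)
  similarity, no Wang-style or vector-space measures.
* Single-linkage chaining makes its dendrograms poor summaries here; it is
  provided for comparison only.
* The Resnik-IC denominator convention (genes vs annotation rows) shifts
  IC_R by a constant; results for Resnik-normalized depend on that choice
  (documented above), Lin does not.
* FCT enumerates child combinations; with very high-degree representatives
  and large k this is combinatorial. The defaults (k = 2) keep it quadratic.
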