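import math

import numpy as np
import pytest

import gsasynth as gs
from gsasynth.annotations import AnnotationCorpus
from gsasynth.errors import ValidationError
from conftest import small_instance

NINE = tuple(sorted(gs.MEASURES))


def tables(g, c):
    return {
        "ic_r": gs.ic_resnik(g, c),
        "ic_s": gs.ic_seco(g),
        "ic_gou": gs.ic_gou(g),
    }


# Hand-evaluated on the toy5 fixture: C and D are sibling leaves under A,
# C and E share only the root.  aic(C,E): shared ancestors {R} with SW(R)=1,
# ancestor weight sums 2.6429 and 2.3458, so 2/4.9887 = 0.4009.
TOY_EXPECTED = {
    "ganesan": (0.5, 0.0),
    "lc": (1 - math.log(3) / math.log(5), 0.0),
    "ps": (1 / 3, 0.0),
    "zhou": (0.15869, 0.0),  # (C,E) raw is negative, clamped in the matrix
    "resnik": (0.2075, 0.0),
    "lin": (0.2075, 0.0),
    "nunivers": (0.5, 0.0),
    "df": (0.5, 0.2),
    "aic": (0.7454, 0.4009),
}


class TestToyValues:
    @pytest.mark.parametrize("measure", NINE)
    def test_hand_derived_pairs(self, toy_graph, toy_corpus, measure):
        m = gs.build_matrix(measure, sorted(toy_graph.terms), toy_graph,
                            **tables(toy_graph, toy_corpus))
        exp_cd, exp_ce = TOY_EXPECTED[measure]
        assert m.sim("C", "D") == pytest.approx(exp_cd, abs=1e-3)
        assert m.sim("C", "E") == pytest.approx(exp_ce, abs=1e-3)

    @pytest.mark.parametrize("measure", NINE)
    def test_unit_diagonal(self, toy_graph, toy_corpus, measure):
        m = gs.build_matrix(measure, sorted(toy_graph.terms), toy_graph,
                            **tables(toy_graph, toy_corpus))
        assert np.all(np.diag(m.values) == 1.0)

    def test_nunivers_matrix_shape_and_entry(self, toy_graph, toy_corpus):
        m = gs.build_matrix("nunivers", sorted(toy_graph.terms), toy_graph,
                            **tables(toy_graph, toy_corpus))
        assert m.values.shape == (6, 6)
        assert m.sim("C", "D") == 0.5


class TestMatrixContracts:
    def test_duplicate_terms_rejected(self, toy_graph, toy_corpus):
        with pytest.raises(ValidationError):
            gs.build_matrix("df", ["C", "C"], toy_graph)

    def test_single_term_rejected(self, toy_graph):
        with pytest.raises(ValidationError):
            gs.build_matrix("df", ["C"], toy_graph)

    def test_unknown_measure_rejected(self, toy_graph):
        with pytest.raises(ValidationError):
            gs.build_matrix("wang", ["C", "D"], toy_graph)

    def test_failing_pair_is_named(self, toy_graph):
        c = gs.propagate(
            AnnotationCorpus(direct=frozenset({("g1", "C", "EXP")})), toy_graph
        )
        ic_r = gs.ic_resnik(toy_graph, c)  # E has no value
        with pytest.raises(Exception, match="E"):
            gs.build_matrix("lin", ["C", "E"], toy_graph, ic_r=ic_r)

    def test_to_distance_round_trip(self, toy_graph, toy_corpus):
        m = gs.build_matrix("df", sorted(toy_graph.terms), toy_graph)
        d = m.to_distance()
        assert np.all(np.diag(d) == 0.0)
        assert np.allclose(1.0 - d - np.eye(len(m.terms)) * (1.0 - np.diag(m.values)),
                           m.values)
        assert np.allclose(1.0 - (1.0 - m.values), m.values)

    def test_tsv_serialization(self, toy_graph, tmp_path):
        m = gs.build_matrix("df", sorted(toy_graph.terms), toy_graph)
        path = tmp_path / "m.tsv"
        m.write_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t")[1:] == list(m.terms)
        assert len(lines) == len(m.terms) + 1


@pytest.mark.parametrize("seed", range(20))
def test_measure_axioms_on_random_ontologies(seed):
    """Symmetry, [0,1] range, and unit diagonal for all nine measures."""
    g, c = small_instance(seed, n_terms=12)
    tbl = tables(g, c)
    terms = sorted(t for t in g.terms if t in tbl["ic_r"])[:8]
    if len(terms) < 2:
        pytest.skip("degenerate corpus")
    for measure in NINE:
        m = gs.build_matrix(measure, terms, g, **tbl)
        assert np.allclose(m.values, m.values.T)
        assert np.all((m.values >= 0.0) & (m.values <= 1.0))
        assert np.all(np.diag(m.values) == 1.0)


class TestCorpusDependence:
    """Edge-based measures see only the DAG; extrinsic-IC measures see the corpus."""

    def alt_corpus(self, g):
        direct = frozenset(
            [("g1", "C", "EXP"), ("g2", "D", "EXP"), ("g3", "E", "EXP"), ("g4", "E", "EXP")]
        )
        return gs.propagate(AnnotationCorpus(direct=direct), g)

    @pytest.mark.parametrize("measure", ["ganesan", "lc", "ps", "df", "nunivers", "zhou"])
    def test_corpus_free_measures_invariant(self, toy_graph, toy_corpus, measure):
        terms = sorted(toy_graph.terms)
        m1 = gs.build_matrix(measure, terms, toy_graph, **tables(toy_graph, toy_corpus))
        m2 = gs.build_matrix(measure, terms, toy_graph,
                             **tables(toy_graph, self.alt_corpus(toy_graph)))
        assert np.array_equal(m1.values, m2.values)

    @pytest.mark.parametrize("measure", ["resnik", "lin", "aic"])
    def test_extrinsic_measures_shift_with_corpus(self, toy_graph, toy_corpus, measure):
        terms = sorted(toy_graph.terms)
        m1 = gs.build_matrix(measure, terms, toy_graph, **tables(toy_graph, toy_corpus))
        m2 = gs.build_matrix(measure, terms, toy_graph,
                             **tables(toy_graph, self.alt_corpus(toy_graph)))
        assert not np.array_equal(m1.values, m2.values)


@pytest.mark.parametrize("seed", range(5))
def test_lin_upper_bound_and_equality_condition(seed):
    """lin <= 1, with equality only when both terms and their MICA share one IC."""
    g, c = small_instance(seed, n_terms=15)
    ic_r = gs.ic_resnik(g, c)
    terms = sorted(t for t in g.terms if t in ic_r)[:10]
    for t1 in terms:
        for t2 in terms:
            if t1 == t2:
                continue
            s = gs.similarity.sim_lin(ic_r, g, t1, t2)
            assert s <= 1.0 + 1e-12
            if s == pytest.approx(1.0):
                a = gs.mica(g, ic_r, t1, t2)
                assert ic_r[t1] == pytest.approx(ic_r[t2])
                assert ic_r[t1] == pytest.approx(ic_r[a])


def test_nunivers_accepts_extrinsic_ic_variant(toy_graph, toy_corpus):
    ic_r = gs.ic_resnik(toy_graph, toy_corpus)
    s = gs.similarity.sim_nunivers(ic_r, toy_graph, "C", "D")
    assert s == pytest.approx(ic_r["A"] / ic_r["C"])
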