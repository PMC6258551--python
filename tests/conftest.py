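import pytest

import gsasynth as gs


@pytest.fixture(scope="session")
def toy():
    """The 6-term hand-checked ontology and its 4-gene propagated corpus."""
    return gs.toy5()


@pytest.fixture(scope="session")
def toy_graph(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_corpus(toy):
    return toy[1]


def small_instance(seed, n_terms=12, n_genes=20):
    """Random DAG + propagated corpus pair for property tests."""
    spec = gs.FixtureSpec(
        n_terms=n_terms, max_parents=2, n_genes=n_genes,
        annotations_per_gene=3.0, seed=seed,
    )
    g = gs.random_dag(spec)
    c = gs.propagate(gs.random_corpus(g, spec), g)
    return g, c
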