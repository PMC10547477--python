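import numpy as np
import pandas as pd
import pytest

from phenofun import fixtures
from phenofun.ontology import GeneAnnotationSet, OntologyGraph, TermInfo


def make_graph(edges, namespaces=None, obsolete=(), alt_ids=None):
    """Build a small ontology from (child, parent, relation) triples."""
    terms = {}
    for c, p, _ in edges:
        for t in (c, p):
            terms.setdefault(t, None)
    namespaces = namespaces or {}
    infos = {
        t: TermInfo(name=t, namespace=namespaces.get(t, "BP"), obsolete=t in obsolete)
        for t in terms
    }
    for t in obsolete:
        infos.setdefault(t, TermInfo(name=t, namespace=namespaces.get(t, "BP"), obsolete=True))
    return OntologyGraph(infos, edges, alt_ids)


@pytest.fixture(scope="session")
def chain_graph():
    """R <- A <- B via is_a."""
    return make_graph([("A", "R", "is_a"), ("B", "A", "is_a")])


@pytest.fixture(scope="session")
def diamond_graph():
    """R <- {A, B} <- C: two paths from C to R."""
    return make_graph(
        [("A", "R", "is_a"), ("B", "R", "is_a"), ("C", "A", "is_a"), ("C", "B", "is_a")]
    )


@pytest.fixture(scope="session")
def eight_term_graph():
    """The documented 8-term similarity fixture.

    R <- {A, B}; A <- {A1, A2}; B <- B1; A1 <- A11; B1 <- B11 (part_of).
    """
    return make_graph(
        [
            ("A", "R", "is_a"),
            ("B", "R", "is_a"),
            ("A1", "A", "is_a"),
            ("A2", "A", "is_a"),
            ("B1", "B", "is_a"),
            ("A11", "A1", "is_a"),
            ("B11", "B1", "part_of"),
        ]
    )


@pytest.fixture(scope="session")
def default_spec():
    return fixtures.FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def fixture_ontology(default_spec):
    return fixtures.make_ontology(default_spec)


@pytest.fixture(scope="session")
def fixture_phenotypes(default_spec):
    return fixtures.make_phenotypes(default_spec)


def random_dag_annotations(seed, n_terms=100, n_genes=50):
    """A random propagation fixture independent of FixtureSpec plumbing."""
    rng = np.random.default_rng(seed)
    ids = [f"GO:{seed % 89 + 10:02d}{i:05d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_par = 1 + (rng.random() < 0.3)
        parents = rng.choice(i, size=min(n_par, i), replace=False)
        for k, j in enumerate(parents):
            rel = "is_a" if k == 0 else ("part_of" if rng.random() < 0.4 else "is_a")
            edges.append((ids[i], ids[int(j)], rel))
    graph = make_graph(edges)
    ann = GeneAnnotationSet()
    for g in range(n_genes):
        for t in rng.choice(n_terms - 1, size=int(rng.integers(1, 6)), replace=False):
            ann.add(f"g{g}", ids[int(t) + 1], "IDA")
    return graph, ann
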