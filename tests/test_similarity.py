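import itertools

import numpy as np
import pytest

from phenofun import fixtures
from phenofun.ontology import GeneAnnotationSet
from phenofun.similarity import (
    EdgeWeights,
    SimilarityError,
    all_vs_all_gogo,
    cross_dataset_gogo,
    gene_pair_gogo,
    semantic_value_sum,
    semantic_values,
    term_similarity,
)

from conftest import make_graph

# frozen values from explicit-path-enumeration oracle on the 8-term fixture
CHAIN_W = 1 / 1.67 + 0.4  # single-child parents
SIM_A11_A2 = 0.4781078329538629
SIM_A11_B11 = 0.18860800141122522
BMA_DISJOINT = 0.21006284784240017


def oracle_svmap(term, graph, weights=None):
    """Independent S-values: enumerate every upward path explicitly."""
    weights = weights or EdgeWeights()
    s = {term: 1.0}

    def walk(node, prod):
        for parent, rel in graph._parents[node]:
            if rel not in ("is_a", "part_of"):
                continue
            val = prod * weights.weight(graph, parent, rel)
            if val > s.get(parent, 0.0):
                s[parent] = val
            walk(parent, val)

    walk(term, 1.0)
    return s


class TestSemanticValues:
    def test_root_term(self, eight_term_graph):
        assert semantic_values("R", eight_term_graph) == {"R": 1.0}

    def test_chain_decay(self, chain_graph):
        s = semantic_values("B", chain_graph)
        assert s["B"] == 1.0
        assert s["A"] == pytest.approx(CHAIN_W)
        assert s["R"] == pytest.approx(CHAIN_W**2)
        assert semantic_value_sum(s) == pytest.approx(1 + CHAIN_W + CHAIN_W**2)

    def test_diamond_takes_max_not_sum(self, diamond_graph):
        s = semantic_values("C", diamond_graph)
        w = 1 / (0.67 + 1) + 0.4  # A and B each have one child
        w_root = 1 / (0.67 + 2) + 0.4  # root has two children
        assert s["A"] == pytest.approx(w)
        assert s["R"] == pytest.approx(w * w_root)  # max of two equal paths, not their sum

    def test_obsolete_term_rejected(self):
        g = make_graph([("A", "R", "is_a")], obsolete={"Z"})
        with pytest.raises(SimilarityError):
            semantic_values("Z", g)

    def test_matches_path_enumeration_oracle(self, eight_term_graph, fixture_ontology):
        graph, _, _ = fixture_ontology
        for g, terms in [(eight_term_graph, eight_term_graph.terms)]:
            for t in terms:
                s = semantic_values(t, g)
                o = oracle_svmap(t, g)
                assert set(s) == set(o)
                for a in o:
                    assert s[a] == pytest.approx(o[a], abs=1e-9)
        # random fixture terms (<=50 sampled)
        rng = np.random.default_rng(0)
        sample = rng.choice(sorted(graph.terms), size=50, replace=False)
        for t in sample:
            s = semantic_values(t, graph)
            o = oracle_svmap(t, graph)
            for a in o:
                assert s[a] == pytest.approx(o[a], abs=1e-9)


class TestTermSimilarity:
    def test_identity(self, eight_term_graph):
        assert term_similarity("A11", "A11", eight_term_graph) == 1.0

    def test_root_only_overlap(self, eight_term_graph):
        s = term_similarity("A11", "B11", eight_term_graph)
        assert s == pytest.approx(SIM_A11_B11, abs=1e-9)
        # equals the root contribution over the SV sums
        s1 = semantic_values("A11", eight_term_graph)
        s2 = semantic_values("B11", eight_term_graph)
        expect = (s1["R"] + s2["R"]) / (semantic_value_sum(s1) + semantic_value_sum(s2))
        assert s == pytest.approx(expect)

    def test_symmetry(self, eight_term_graph):
        terms = [t for t in eight_term_graph.terms]
        for t1, t2 in itertools.combinations(terms, 2):
            assert term_similarity(t1, t2, eight_term_graph) == pytest.approx(
                term_similarity(t2, t1, eight_term_graph)
            )

    def test_cross_namespace_error(self):
        g = make_graph(
            [("A", "R", "is_a"), ("X", "S", "is_a")],
            namespaces={"X": "MF", "S": "MF"},
        )
        with pytest.raises(SimilarityError, match="cross-namespace"):
            term_similarity("A", "X", g)

    def test_bounded(self, fixture_ontology):
        graph, ann, _ = fixture_ontology
        rng = np.random.default_rng(1)
        bp = [t for t in graph.terms if graph.namespace(t) == "BP"]
        for _ in range(100):
            t1, t2 = rng.choice(bp, size=2)
            s = term_similarity(t1, t2, graph)
            assert 0.0 < s <= 1.0 + 1e-12


class TestGenePairGogo:
    def test_identical_sets_score_one(self, eight_term_graph):
        assert gene_pair_gogo({"A11", "A2"}, {"A11", "A2"}, eight_term_graph) == pytest.approx(1.0)

    def test_disjoint_branches_low(self, eight_term_graph):
        s = gene_pair_gogo({"A11", "A2"}, {"B11"}, eight_term_graph)
        assert s == pytest.approx(BMA_DISJOINT, abs=1e-6)
        assert s < 0.3

    def test_symmetric(self, eight_term_graph):
        a, b = {"A11", "A2"}, {"B11", "B1"}
        assert gene_pair_gogo(a, b, eight_term_graph) == pytest.approx(
            gene_pair_gogo(b, a, eight_term_graph)
        )

    def test_empty_set_is_no_score(self, eight_term_graph):
        assert gene_pair_gogo(set(), {"A11"}, eight_term_graph) is None


class TestAllVsAll:
    def test_pair_counting_excludes_self(self, eight_term_graph):
        sets = {"g1": {"A11"}, "g2": {"A2"}, "g3": {"B11"}}
        out = all_vs_all_gogo(sets, None, eight_term_graph, namespaces=("BP",))
        assert len(out) == 3
        assert not ((out.geneA == out.geneB).any())

    def test_namespace_empty_set_omitted(self):
        g = make_graph(
            [("A", "R", "is_a"), ("B", "R", "is_a"), ("X", "S", "is_a"), ("Y", "S", "is_a")],
            namespaces={"X": "MF", "Y": "MF", "S": "MF"},
        )
        ann = GeneAnnotationSet(
            {"g1": [("A", "IDA"), ("X", "IDA")], "g2": [("B", "IDA"), ("Y", "IDA")], "g3": [("A", "IDA")]}
        )
        out = all_vs_all_gogo(ann, None, g, namespaces=("BP", "MF"))
        mf = out.loc[out.namespace == "MF"]
        bp = out.loc[out.namespace == "BP"]
        assert set(bp.geneA) | set(bp.geneB) == {"g1", "g2", "g3"}
        assert set(mf.geneA) | set(mf.geneB) == {"g1", "g2"}  # g3 has no MF terms

    def test_scores_bounded_and_symmetric_storage(self, fixture_ontology):
        graph, ann, _ = fixture_ontology
        sub = GeneAnnotationSet({g: ann[g] for g in ann.genes[:15]})
        out = all_vs_all_gogo(sub, None, graph, namespaces=("BP",))
        assert ((out.score > 0) & (out.score <= 1.0 + 1e-12)).all()
        assert (out.geneA < out.geneB).all()

    def test_shuffled_annotations_score_lower(self, fixture_ontology):
        """Within-module pairs lose their similarity when gene-term-set
        assignments are shuffled (real-vs-random separation)."""
        from scipy.stats import mannwhitneyu

        graph, ann, truth = fixture_ontology
        mods = truth["modules"]
        genes = ann.genes
        sets = {g: ann.term_set(g) for g in genes}
        real = all_vs_all_gogo(sets, None, graph, namespaces=("BP",))
        rng = np.random.default_rng(11)
        perm = rng.permutation(genes)
        shuffled_sets = {g: sets[p] for g, p in zip(genes, perm)}
        shuf = all_vs_all_gogo(shuffled_sets, None, graph, namespaces=("BP",))
        same = [mods[a] == mods[b] for a, b in real[["geneA", "geneB"]].itertuples(index=False)]
        real_scores = real.loc[same, "score"]
        shuf_scores = shuf.loc[same, "score"]
        stat = mannwhitneyu(real_scores, shuf_scores, alternative="greater")
        assert stat.pvalue < 0.01


def test_cross_dataset_same_gene_agreement(fixture_ontology):
    graph, ann, _ = fixture_ontology
    sub = GeneAnnotationSet({g: ann[g] for g in ann.genes[:10]})
    out = cross_dataset_gogo(sub, sub, graph, namespaces=("BP",))
    assert np.allclose(out["score"], 1.0)  # identical datasets agree perfectly


def test_wang_preset_fixed_weights(chain_graph):
    s = semantic_values("B", chain_graph, EdgeWeights.wang())
    assert s["A"] == pytest.approx(0.8)
    assert s["R"] == pytest.approx(0.64)
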