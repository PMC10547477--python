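"""Wang-style GO semantic similarity with child-count-weighted edges (GOGO).

A term's *semantic value map* assigns each ancestor a contribution S(a) that
decays along edges toward the root; an edge into parent ``a`` carries weight
w = 1/(c + nc(a)) + w0(relation), where nc(a) is a's direct child count, so
contributions decay faster through densely branched regions of the DAG.
Term-level similarity is the shared-ancestor overlap of two S-maps, and
gene-level similarity is a best-match average over the two term sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

from .ontology import HIERARCHY_RELATIONS, GeneAnnotationSet, OntologyGraph

logger = logging.getLogger(__name__)


class SimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class EdgeWeights:
    """Edge-weight scheme for semantic-value decay.

    The default is the child-count-aware scheme (c=0.67, w0 = 0.4 for is_a /
    0.3 for part_of). ``fixed`` switches to the classic Wang constants
    (0.8 / 0.6) ignoring child counts.
    """

    c: float = 0.67
    w0_is_a: float = 0.4
    w0_part_of: float = 0.3
    fixed: bool = False
    fixed_is_a: float = 0.8
    fixed_part_of: float = 0.6

    @classmethod
    def wang(cls) -> "EdgeWeights":
        return cls(fixed=True)

    def weight(self, graph: OntologyGraph, parent: str, relation: str) -> float:
        if self.fixed:
            w = self.fixed_is_a if relation == "is_a" else self.fixed_part_of
        else:
            w0 = self.w0_is_a if relation == "is_a" else self.w0_part_of
            w = 1.0 / (self.c + graph.n_children(parent, HIERARCHY_RELATIONS)) + w0
        if w >= 1.0:
            logger.warning("edge weight %.3f >= 1 into %s; clamping to 0.999", w, parent)
            w = 0.999
        return w


def semantic_values(
    term: str, graph: OntologyGraph, weights: EdgeWeights | None = None
) -> dict[str, float]:
    """S-value of every ancestor-or-self of ``term``.

    S(term) = 1 and S(a) = max over children c of a lying on a path toward
    ``term`` of w(c -> a) * S(c); only is_a/part_of edges are traversed.
    """
    weights = weights or EdgeWeights()
    if term not in graph:
        raise SimilarityError(f"unknown term: {term}")
    if graph.is_obsolete(term):
        raise SimilarityError(f"obsolete term: {term}")
    anc = graph.ancestors(term, HIERARCHY_RELATIONS, include_self=True)
    s: dict[str, float] = {term: 1.0}

    def value(a: str) -> float:
        if a in s:
            return s[a]
        best = 0.0
        for child, rel in graph._children[a]:
            if rel in HIERARCHY_RELATIONS and child in anc:
                w = weights.weight(graph, a, rel)
                best = max(best, w * value(child))
        s[a] = best
        return best

    for a in anc:
        value(a)
    return s


def semantic_value_sum(svmap: dict[str, float]) -> float:
    return sum(svmap.values())


def term_similarity(
    t1: str,
    t2: str,
    graph: OntologyGraph,
    weights: EdgeWeights | None = None,
    _cache: dict | None = None,
) -> float:
    """Shared-ancestor similarity of two terms in [0, 1]; symmetric; 1 iff equal."""
    if graph.namespace(t1) != graph.namespace(t2):
        raise SimilarityError(
            f"cross-namespace term pair: {t1} ({graph.namespace(t1)}) vs {t2} ({graph.namespace(t2)})"
        )
    if _cache is not None:
        key = ("pair", t1, t2) if t1 <= t2 else ("pair", t2, t1)
        if key in _cache:
            return _cache[key]
        if t1 not in _cache:
            _cache[t1] = semantic_values(t1, graph, weights)
        if t2 not in _cache:
            _cache[t2] = semantic_values(t2, graph, weights)
        sv1, sv2 = _cache[t1], _cache[t2]
    else:
        sv1 = semantic_values(t1, graph, weights)
        sv2 = semantic_values(t2, graph, weights)
    shared = sv1.keys() & sv2.keys()
    num = sum(sv1[a] + sv2[a] for a in shared)
    den = semantic_value_sum(sv1) + semantic_value_sum(sv2)
    score = num / den
    if _cache is not None:
        _cache[key] = score
    return score


def gene_pair_gogo(
    set_a: set[str],
    set_b: set[str],
    graph: OntologyGraph,
    weights: EdgeWeights | None = None,
    _cache: dict | None = None,
) -> float | None:
    """Best-match-average similarity of two term sets; None for an empty set.

    BMA = (sum over a in A of max_b sim(a,b) + sum over b in B of max_a
    sim(a,b)) / (|A| + |B|); equals 1 for identical sets, 0 would require
    disjoint ancestries (impossible within one namespace, where the root is
    always shared).
    """
    if not set_a or not set_b:
        return None
    sims: dict[tuple[str, str], float] = {}
    for a in set_a:
        for b in set_b:
            sims[(a, b)] = 1.0 if a == b else term_similarity(a, b, graph, weights, _cache)
    best_a = sum(max(sims[(a, b)] for b in set_b) for a in set_a)
    best_b = sum(max(sims[(a, b)] for a in set_a) for b in set_b)
    return (best_a + best_b) / (len(set_a) + len(set_b))


def all_vs_all_gogo(
    geneset1: GeneAnnotationSet | dict[str, set[str]],
    geneset2: GeneAnnotationSet | dict[str, set[str]] | None,
    graph: OntologyGraph,
    namespaces: tuple[str, ...] = ("BP", "MF"),
    weights: EdgeWeights | None = None,
    include_self: bool = False,
) -> pd.DataFrame:
    """All-vs-all gene-pair similarity table.

    With a single gene set, scores all unordered within-set pairs; with two,
    scores the cross product (deduplicated to unordered pairs). Genes with an
    empty term set in a namespace are omitted from that namespace's rows.
    Returns columns (geneA, geneB, namespace, score).
    """

    def as_sets(gs) -> dict[str, set[str]]:
        if isinstance(gs, GeneAnnotationSet):
            return {g: gs.term_set(g) for g in gs.genes}
        return {g: set(v) for g, v in gs.items()}

    sets1 = as_sets(geneset1)
    sets2 = sets1 if geneset2 is None else as_sets(geneset2)
    within = geneset2 is None

    rows = []
    for ns in namespaces:
        cache: dict = {}

        def ns_set(terms: set[str]) -> set[str]:
            return {
                t for t in terms
                if t in graph and not graph.is_obsolete(t) and graph.namespace(t) == ns
            }

        ns1 = {g: s for g, s in ((g, ns_set(t)) for g, t in sets1.items()) if s}
        ns2 = ns1 if within else {g: s for g, s in ((g, ns_set(t)) for g, t in sets2.items()) if s}
        if within:
            pairs = list(itertools.combinations(sorted(ns1), 2))
            if include_self:
                pairs += [(g, g) for g in sorted(ns1)]
        else:
            pairs = [
                (a, b) for a in sorted(ns1) for b in sorted(ns2) if include_self or a != b
            ]
        for a, b in pairs:
            score = gene_pair_gogo(ns1[a], ns2[b], graph, weights, cache)
            rows.append((a, b, ns, score))
    return pd.DataFrame(rows, columns=["geneA", "geneB", "namespace", "score"])


def cross_dataset_gogo(
    annot_a: GeneAnnotationSet | dict[str, set[str]],
    annot_b: GeneAnnotationSet | dict[str, set[str]],
    graph: OntologyGraph,
    namespaces: tuple[str, ...] = ("BP", "MF"),
    weights: EdgeWeights | None = None,
) -> pd.DataFrame:
    """Same-gene similarity between two annotation sets of the same genes.

    For every gene present in both inputs, compares the gene's term set from
    dataset A against its term set from dataset B (per namespace), yielding a
    per-gene agreement score — the dataset-vs-dataset comparison used to
    benchmark predicted against curated annotations.
    """

    def as_sets(gs):
        if isinstance(gs, GeneAnnotationSet):
            return {g: gs.term_set(g) for g in gs.genes}
        return {g: set(v) for g, v in gs.items()}

    sa, sb = as_sets(annot_a), as_sets(annot_b)
    rows = []
    for ns in namespaces:
        cache: dict = {}
        for g in sorted(sa.keys() & sb.keys()):
            ta = {t for t in sa[g] if t in graph and not graph.is_obsolete(t) and graph.namespace(t) == ns}
            tb = {t for t in sb[g] if t in graph and not graph.is_obsolete(t) and graph.namespace(t) == ns}
            if not ta or not tb:
                continue
            rows.append((g, ns, gene_pair_gogo(ta, tb, graph, weights, cache)))
    return pd.DataFrame(rows, columns=["gene", "namespace", "score"])
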