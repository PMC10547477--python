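"""Gene Ontology DAG handling: parsing, annotation closure, information content.

The ontology is held as a typed DAG over GO term identifiers. Annotation sets
are closed upward along a configurable relation set (by default ``is_a``,
``part_of``, ``has_part`` and ``regulates``), and term information content is
computed as IC(t) = -log p(t), where p(t) is the fraction of annotation
records falling on t or any of its descendants.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping

import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: relations used when closing annotation sets upward
PROPAGATION_RELATIONS = frozenset({"is_a", "part_of", "has_part", "regulates"})
#: relations that define the subsumption hierarchy used for descendant
#: counting in IC and for semantic-similarity ancestry; has_part/regulates
#: cross or invert the specificity semantics and are excluded here
HIERARCHY_RELATIONS = frozenset({"is_a", "part_of"})

_NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}


class OntologyError(ValueError):
    pass


@dataclass(frozen=True)
class TermInfo:
    name: str
    namespace: str
    obsolete: bool = False


class OntologyGraph:
    """A typed GO DAG.

    Edges run child -> parent, labelled with a relation. The graph is
    validated to be acyclic over the hierarchy relations, and every
    non-obsolete, non-root term must reach its namespace root via ``is_a``.
    """

    def __init__(
        self,
        terms: Mapping[str, TermInfo],
        edges: Iterable[tuple[str, str, str]],
        alt_ids: Mapping[str, str] | None = None,
    ):
        self.terms: dict[str, TermInfo] = dict(terms)
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self._parents: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        self._children: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        for child, parent, rel in edges:
            for t in (child, parent):
                if t not in self.terms:
                    raise OntologyError(f"edge references unknown term: {t}")
            self._parents[child].append((parent, rel))
            self._children[parent].append((child, rel))
        self._check_acyclic()
        self._roots: dict[str, str] = {}
        for t, info in self.terms.items():
            if info.obsolete:
                continue
            if not any(r in HIERARCHY_RELATIONS for _, r in self._parents[t]):
                ns = info.namespace
                if ns in self._roots and self._roots[ns] != t:
                    logger.warning("namespace %s has multiple roots: %s, %s", ns, self._roots[ns], t)
                self._roots.setdefault(ns, t)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term: str) -> str:
        """Map an alt_id onto its primary identifier (identity otherwise)."""
        return self.alt_ids.get(term, term)

    def namespace(self, term: str) -> str:
        return self.terms[term].namespace

    def is_obsolete(self, term: str) -> bool:
        return self.terms[term].obsolete

    def root(self, namespace: str) -> str:
        return self._roots[_NAMESPACE_CODES.get(namespace, namespace)]

    @property
    def roots(self) -> dict[str, str]:
        return dict(self._roots)

    def parents(self, term: str, relations: frozenset = HIERARCHY_RELATIONS) -> list[str]:
        return [p for p, r in self._parents[term] if r in relations]

    def children(self, term: str, relations: frozenset = HIERARCHY_RELATIONS) -> list[str]:
        return [c for c, r in self._children[term] if r in relations]

    def n_children(self, term: str, relations: frozenset = HIERARCHY_RELATIONS) -> int:
        return len(self.children(term, relations))

    def ancestors(
        self, term: str, relations: frozenset = HIERARCHY_RELATIONS, include_self: bool = False
    ) -> set[str]:
        """All terms reachable upward from ``term`` along ``relations``."""
        if term not in self.terms:
            raise OntologyError(f"unknown term: {term}")
        seen: set[str] = {term}
        queue = deque([term])
        while queue:
            cur = queue.popleft()
            for p in self.parents(cur, relations):
                if p not in seen:
                    seen.add(p)
                    queue.append(p)
        if not include_self:
            seen.discard(term)
        return seen

    def descendants(
        self, term: str, relations: frozenset = HIERARCHY_RELATIONS, include_self: bool = False
    ) -> set[str]:
        if term not in self.terms:
            raise OntologyError(f"unknown term: {term}")
        seen: set[str] = {term}
        queue = deque([term])
        while queue:
            cur = queue.popleft()
            for c in self.children(cur, relations):
                if c not in seen:
                    seen.add(c)
                    queue.append(c)
        if not include_self:
            seen.discard(term)
        return seen

    def _check_acyclic(self) -> None:
        # Kahn's algorithm over hierarchy edges
        indeg = {t: 0 for t in self.terms}
        for child in self.terms:
            for p, r in self._parents[child]:
                if r in HIERARCHY_RELATIONS:
                    indeg[p] += 1
        queue = deque(t for t, d in indeg.items() if d == 0)
        seen = 0
        while queue:
            cur = queue.popleft()
            seen += 1
            for p, r in self._parents[cur]:
                if r in HIERARCHY_RELATIONS:
                    indeg[p] -= 1
                    if indeg[p] == 0:
                        queue.append(p)
        if seen != len(self.terms):
            raise OntologyError("cycle detected over is_a/part_of edges")

    def topological_order(self) -> list[str]:
        """Terms ordered so every term precedes its hierarchy ancestors."""
        indeg = {t: 0 for t in self.terms}
        for child in self.terms:
            for p, r in self._parents[child]:
                if r in HIERARCHY_RELATIONS:
                    indeg[p] += 1
        queue = deque(sorted(t for t, d in indeg.items() if d == 0))
        order = []
        while queue:
            cur = queue.popleft()
            order.append(cur)
            for p, r in self._parents[cur]:
                if r in HIERARCHY_RELATIONS:
                    indeg[p] -= 1
                    if indeg[p] == 0:
                        queue.append(p)
        return order


def load_obo(path) -> OntologyGraph:
    """Read an OBO 1.2 file into an :class:`OntologyGraph`.

    Obsolete terms are kept but flagged (they take no part in propagation);
    ``alt_id`` identifiers are recorded so annotations can be remapped to
    primary ids. A parent id that never appears as a stanza of its own is a
    hard error.
    """
    try:
        g = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - message shape depends on obonet
        raise OntologyError(f"failed to parse OBO file {path}: {exc}") from exc

    terms: dict[str, TermInfo] = {}
    edges: list[tuple[str, str, str]] = []
    alt_ids: dict[str, str] = {}
    dangling: set[str] = set()
    for node, data in g.nodes(data=True):
        if "name" not in data and not data:
            dangling.add(node)
            continue
        ns = _NAMESPACE_CODES.get(data.get("namespace", ""), data.get("namespace", ""))
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        terms[node] = TermInfo(name=data.get("name", node), namespace=ns, obsolete=obsolete)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    if dangling:
        raise OntologyError(f"dangling parent ids (no [Term] stanza): {sorted(dangling)}")
    n_obsolete = 0
    for child, parent, rel in g.edges(keys=True):
        if terms[child].obsolete or terms[parent].obsolete:
            n_obsolete += 1
            continue
        edges.append((child, parent, rel))
    obs = sum(1 for t in terms.values() if t.obsolete)
    if obs:
        logger.warning("%d obsolete terms flagged and excluded from propagation", obs)
    return OntologyGraph(terms, edges, alt_ids)


class GeneAnnotationSet:
    """gene -> set of (GO term, evidence code)."""

    def __init__(self, mapping: Mapping[str, Iterable[tuple[str, str]]] | None = None):
        self._data: dict[str, set[tuple[str, str]]] = {
            g: set(v) for g, v in (mapping or {}).items()
        }

    def add(self, gene: str, term: str, evidence: str = "IEA") -> None:
        self._data.setdefault(gene, set()).add((term, evidence))

    @property
    def genes(self) -> list[str]:
        return sorted(self._data)

    def records(self) -> Iterable[tuple[str, str, str]]:
        for g in sorted(self._data):
            for term, ev in sorted(self._data[g]):
                yield g, term, ev

    def __getitem__(self, gene: str) -> set[tuple[str, str]]:
        return self._data[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._data

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneAnnotationSet) and self._data == other._data

    @property
    def n_records(self) -> int:
        return sum(len(v) for v in self._data.values())

    def term_set(self, gene: str, graph: OntologyGraph | None = None, namespace: str | None = None) -> set[str]:
        terms = {t for t, _ in self._data.get(gene, set())}
        if namespace is not None:
            assert graph is not None, "namespace filtering needs the graph"
            terms = {t for t in terms if graph.namespace(t) == namespace}
        return terms

    def term_sets(self, graph: OntologyGraph | None = None, namespace: str | None = None) -> dict[str, set[str]]:
        return {g: self.term_set(g, graph, namespace) for g in self._data}

    def filter_evidence(
        self,
        exclude: frozenset = frozenset({"NAS", "ND", "TAS", "IEA"}),
        keep_substrings: tuple[str, ...] = ("UniProtKB-KW", "UniProtKB-kw"),
    ) -> "GeneAnnotationSet":
        """Drop records by evidence code, keeping curated-keyword IEA records.

        An evidence string containing one of ``keep_substrings`` (e.g.
        ``IEA:UniProtKB-KW``) survives even if its leading code is excluded.
        """
        out = GeneAnnotationSet()
        for g, term, ev in self.records():
            code = ev.split(":", 1)[0].split("|", 1)[0]
            if code in exclude and not any(s in ev for s in keep_substrings):
                continue
            out.add(g, term, ev)
        return out

    def remap_alt_ids(self, graph: OntologyGraph) -> "GeneAnnotationSet":
        out = GeneAnnotationSet()
        for g, term, ev in self.records():
            out.add(g, graph.resolve(term), ev)
        return out


def up_propagate(
    annotations: GeneAnnotationSet,
    graph: OntologyGraph,
    relations: frozenset = PROPAGATION_RELATIONS,
) -> GeneAnnotationSet:
    """Close each gene's annotation set under ancestor traversal.

    Propagated records carry the evidence code of the record they came from.
    Obsolete terms are never introduced by propagation. Idempotent.
    """
    unknown = sorted(
        {t for _, t, _ in annotations.records() if graph.resolve(t) not in graph}
    )
    if unknown:
        raise OntologyError(f"annotated terms missing from ontology: {unknown}")
    out = GeneAnnotationSet()
    anc_cache: dict[str, set[str]] = {}
    for gene, term, ev in annotations.records():
        term = graph.resolve(term)
        out.add(gene, term, ev)
        if term not in anc_cache:
            anc_cache[term] = {
                a for a in graph.ancestors(term, relations) if not graph.is_obsolete(a)
            }
        for a in anc_cache[term]:
            out.add(gene, a, ev)
    return out


@dataclass
class ICTable:
    """term -> (annotation probability, information content)."""

    p: dict[str, float]
    ic: dict[str, float]
    base: float | None = None  # None = natural log
    n_records: int = 0

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    @property
    def max_ic(self) -> float:
        return max(self.ic.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, self.p[t], self.ic[t]) for t in sorted(self.ic)]
        return pd.DataFrame(rows, columns=["term", "p", "ic"])


def information_content(
    annotations: GeneAnnotationSet,
    graph: OntologyGraph,
    base: float | None = None,
    relations: frozenset = HIERARCHY_RELATIONS,
    propagate: bool = True,
) -> ICTable:
    """IC(t) = -log p(t) with p(t) = (records on t or any descendant) / N.

    ``N`` is the per-namespace total of annotation records after
    up-propagation (so each namespace root gets p = 1 and IC = 0; BP and MF
    never mix in one frequency). Descendant counting uses the subsumption
    relations only. Terms with zero count are absent from the table.
    """
    if propagate:
        annotations = up_propagate(annotations, graph)
    if annotations.n_records == 0:
        raise OntologyError("empty annotation corpus (N = 0)")
    counts: dict[str, int] = {}
    n_ns: dict[str, int] = {}
    anc_cache: dict[str, set[str]] = {}
    for _, term, _ in annotations.records():
        ns = graph.namespace(term)
        n_ns[ns] = n_ns.get(ns, 0) + 1
        if term not in anc_cache:
            anc_cache[term] = graph.ancestors(term, relations, include_self=True)
        for a in anc_cache[term]:
            counts[a] = counts.get(a, 0) + 1
    log = math.log if base is None else (lambda x: math.log(x, base))
    p = {t: c / n_ns[graph.namespace(t)] for t, c in counts.items()}
    ic = {t: max(0.0, -log(v)) for t, v in p.items()}
    return ICTable(p=p, ic=ic, base=base, n_records=annotations.n_records)


def ic_for_new_terms(predictions: pd.DataFrame, ic: ICTable) -> pd.DataFrame:
    """Attach an ``IC`` column; unseen terms get the corpus maximum IC."""
    if not ic.ic:
        raise OntologyError("empty IC table")
    mx = ic.max_ic
    out = predictions.copy()
    out["IC"] = [ic.ic.get(t, mx) for t in out["term"]]
    return out


def taxon_constrain(
    predictions: pd.DataFrame,
    banned_terms: Iterable[str],
    graph: OntologyGraph | None = None,
    include_descendants: bool = False,
) -> pd.DataFrame:
    """Drop predictions on taxon-banned terms.

    With ``include_descendants`` every descendant of a banned term is banned
    too (requires ``graph``).
    """
    banned = set(banned_terms)
    if include_descendants:
        if graph is None:
            raise ValueError("descendant mode requires the ontology graph")
        extra: set[str] = set()
        for t in banned:
            if t in graph:
                extra |= graph.descendants(t)
        banned |= extra
    if not banned:
        return predictions.copy()
    keep = ~predictions["term"].isin(banned)
    n_removed = int((~keep).sum())
    logger.info("taxon constraint removed %d of %d predictions", n_removed, len(predictions))
    return predictions.loc[keep].reset_index(drop=True)
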