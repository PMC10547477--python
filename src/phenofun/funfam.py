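"""Protein-family homology features and the family-membership decision tree.

Handles hmmsearch ``--domtblout`` hit tables (one row per domain match of a
family HMM against a protein), non-overlapping domain resolution by
bit-score-weighted interval scheduling, the sparse -log10(E) feature matrix,
family-level GO association (member-annotation proportions), and the
fast-and-frugal prediction tree: best resolved family from the primary
library, else from the fallback library, emitting that family's member
proportions as term probabilities.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import sparse

from .ontology import (
    PROPAGATION_RELATIONS,
    GeneAnnotationSet,
    OntologyGraph,
    up_propagate,
)

logger = logging.getLogger(__name__)

#: evidence codes excluded when associating GO terms with families
#: (keyword-curated IEA records are kept; see GeneAnnotationSet.filter_evidence)
EXCLUDED_EVIDENCE = frozenset({"NAS", "ND", "TAS", "IEA"})


class HitParseError(ValueError):
    pass


@dataclass(frozen=True)
class DomainHit:
    """One domain match: 1-based inclusive envelope coordinates."""

    protein: str
    family: str
    evalue: float
    bitscore: float
    start: int
    stop: int
    source: str = "cath"

    def __post_init__(self):
        if self.start > self.stop:
            raise HitParseError(f"hit {self.protein}/{self.family}: start > stop")
        if not self.evalue > 0:
            raise HitParseError(f"hit {self.protein}/{self.family}: E-value must be > 0")
        if not math.isfinite(self.bitscore):
            raise HitParseError(f"hit {self.protein}/{self.family}: non-finite bit score")


def parse_domtbl(path, source: str = "cath") -> list[DomainHit]:
    """Read hmmsearch ``--domtblout`` output (or the equivalent 6-column TSV).

    In domtblout rows the target is the protein sequence and the query the
    family HMM; the per-domain independent E-value (column 13), domain bit
    score (column 14) and envelope coordinates (columns 20-21) are used.
    A tab-separated file with columns (protein, family, evalue, bitscore,
    start, stop) is accepted as a plain-text equivalent.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if "\t" in line:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 6:
                    raise HitParseError(f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}")
                protein, family, ev, bit, start, stop = fields[:6]
            else:
                fields = line.split()
                if len(fields) < 23:
                    raise HitParseError(f"{path}:{lineno}: expected >=23 domtblout columns, got {len(fields)}")
                protein, family = fields[0], fields[3]
                ev, bit = fields[12], fields[13]
                start, stop = fields[19], fields[20]
            try:
                hits.append(
                    DomainHit(protein, family, float(ev), float(bit), int(start), int(stop), source)
                )
            except (ValueError, HitParseError) as exc:
                raise HitParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def filter_hits(hits: Iterable[DomainHit], emax: float = 1e-3) -> list[DomainHit]:
    """Keep hits with E-value strictly below ``emax``."""
    if not emax > 0:
        raise ValueError("emax must be positive")
    return [h for h in hits if h.evalue < emax]


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return min(a.stop, b.stop) - max(a.start, b.start) + 1


def resolve_hits(hits: Sequence[DomainHit], overlap_tolerance: int = 0) -> list[DomainHit]:
    """Maximum-total-bit-score set of pairwise non-overlapping hits.

    Weighted interval scheduling by dynamic programming over hits sorted by
    envelope stop. Two hits conflict when they share more than
    ``overlap_tolerance`` residues. Ties are broken deterministically
    (higher bit, lower E, lexicographic family id).
    """
    proteins = {h.protein for h in hits}
    if len(proteins) > 1:
        raise ValueError(f"resolve_hits expects hits for one protein, got {sorted(proteins)}")
    order = sorted(hits, key=lambda h: (h.stop, h.start, -h.bitscore, h.evalue, h.family))
    n = len(order)
    if n == 0:
        return []
    stops = [h.stop for h in order]
    # pred[i]: rightmost j < i compatible with i (stop_j <= start_i - 1 + tol)
    pred = [bisect_right(stops, order[i].start - 1 + overlap_tolerance, 0, i) - 1 for i in range(n)]
    # best[i]: (total bits, tie-break key, chosen set) over the first i hits
    best_score = [0.0] * (n + 1)
    take = [False] * (n + 1)
    for i in range(1, n + 1):
        h = order[i - 1]
        with_i = h.bitscore + best_score[pred[i - 1] + 1]
        without_i = best_score[i - 1]
        # prefer taking the hit on exact ties: keeps higher-bit hits in play
        take[i] = with_i >= without_i
        best_score[i] = max(with_i, without_i)
    chosen: list[DomainHit] = []
    i = n
    while i > 0:
        if take[i]:
            chosen.append(order[i - 1])
            i = pred[i - 1] + 1
        else:
            i -= 1
    chosen.sort(key=lambda h: (h.start, h.stop, -h.bitscore, h.evalue, h.family))
    return chosen


@dataclass
class FamilyFeatureMatrix:
    """Sparse proteins x families matrix of -log10 E-values."""

    matrix: sparse.csr_matrix
    proteins: list[str]
    families: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def sparsity(self) -> float:
        n, m = self.matrix.shape
        return 1.0 - self.matrix.nnz / (n * m)

    def to_dense(self):
        return self.matrix.toarray()


def build_feature_matrix(
    hits: Iterable[DomainHit],
    proteins: Sequence[str] | None = None,
    families: Sequence[str] | None = None,
) -> FamilyFeatureMatrix:
    """Entry (p, f) = -log10 of the lowest E-value of p's hits to f.

    Hits are assumed pre-filtered at E < 1e-3 so entries exceed 3; ties on
    E-value are broken by higher bit score (irrelevant to the entry value).
    """
    hits = list(hits)
    for h in hits:
        if not h.evalue > 0:
            raise ValueError("E-value must be > 0")
    best: dict[tuple[str, str], DomainHit] = {}
    for h in hits:
        key = (h.protein, h.family)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[key] = h
    proteins = list(proteins) if proteins is not None else sorted({h.protein for h in hits})
    families = list(families) if families is not None else sorted({h.family for h in hits})
    pi = {p: i for i, p in enumerate(proteins)}
    fi = {f: i for i, f in enumerate(families)}
    rows, cols, vals = [], [], []
    for (p, f), h in best.items():
        if p in pi and f in fi:
            rows.append(pi[p])
            cols.append(fi[f])
            vals.append(-math.log10(h.evalue))
    m = sparse.csr_matrix((vals, (rows, cols)), shape=(len(proteins), len(families)))
    return FamilyFeatureMatrix(m, proteins, families)


@dataclass
class FamilyGOTable:
    """family -> term -> (annotated-member count, member count, proportion)."""

    table: dict[str, dict[str, tuple[int, int, float]]]

    def terms(self, family: str) -> dict[str, float]:
        return {t: prop for t, (_, _, prop) in self.table.get(family, {}).items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (f, t, c, n, prop)
            for f, terms in sorted(self.table.items())
            for t, (c, n, prop) in sorted(terms.items())
        ]
        return pd.DataFrame(rows, columns=["family", "term", "annotated", "members", "proportion"])


def associate_family_go(
    membership: Mapping[str, Iterable[str]],
    annotations: GeneAnnotationSet,
    graph: OntologyGraph,
    relations: frozenset = PROPAGATION_RELATIONS,
    exclude_evidence: frozenset = EXCLUDED_EVIDENCE,
) -> FamilyGOTable:
    """Per family, the proportion of members annotated with each term.

    Annotations are evidence-filtered (NAS/ND/TAS/IEA dropped, keyword-curated
    IEA kept) and closed upward along ``relations`` before counting.
    """
    filtered = annotations.filter_evidence(exclude=exclude_evidence)
    closed = up_propagate(filtered, graph, relations)
    table: dict[str, dict[str, tuple[int, int, float]]] = {}
    for family, members in membership.items():
        members = sorted(set(members))
        if not members:
            raise ValueError(f"family {family} has no members")
        counts: dict[str, int] = {}
        for m in members:
            for t in closed.term_set(m) if m in closed else set():
                counts[t] = counts.get(t, 0) + 1
        table[family] = {
            t: (c, len(members), c / len(members)) for t, c in counts.items()
        }
    return FamilyGOTable(table)


def _best_resolved_family(
    hits: Sequence[DomainHit],
    emax: float,
    inclusion_thresholds: Mapping[str, float] | None,
) -> str | None:
    """Best-bit family among the resolved significant hits, or None."""
    if inclusion_thresholds is not None:
        sig = [h for h in hits if h.bitscore >= inclusion_thresholds.get(h.family, math.inf)]
    else:
        sig = filter_hits(hits, emax)
    if not sig:
        return None
    resolved = resolve_hits(sig)
    best = min(resolved, key=lambda h: (-h.bitscore, h.evalue, h.family))
    return best.family


def cathpredict(
    cath_hits: Iterable[DomainHit],
    pfam_hits: Iterable[DomainHit],
    cath_go: FamilyGOTable,
    pfam_go: FamilyGOTable,
    pmin: float = 0.1,
    emax: float = 1e-3,
    inclusion_thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Fast-and-frugal family-membership predictor.

    Per protein: if it has at least one significant resolved hit to the
    primary (CATH-style) library, the single best-bit family's member
    proportions become term probabilities; otherwise the fallback
    (Pfam-style) library is tried the same way; otherwise nothing is
    emitted. Predictions with probability < ``pmin`` (strict) are dropped.
    Without a per-family bit-score ``inclusion_thresholds`` table, the
    E < ``emax`` filter stands in as the significance gate.
    """
    by_protein: dict[str, dict[str, list[DomainHit]]] = {}
    for h in cath_hits:
        by_protein.setdefault(h.protein, {"cath": [], "pfam": []})["cath"].append(h)
    for h in pfam_hits:
        by_protein.setdefault(h.protein, {"cath": [], "pfam": []})["pfam"].append(h)

    rows = []
    for protein in sorted(by_protein):
        for branch, go_table in (("cath", cath_go), ("pfam", pfam_go)):
            fam = _best_resolved_family(by_protein[protein][branch], emax, inclusion_thresholds)
            if fam is None:
                continue
            for term, prop in sorted(go_table.terms(fam).items()):
                if prop < pmin:
                    continue
                rows.append((protein, term, prop, "cathpredict", fam, branch))
            break  # one exit per question: stop at the first matched library
    return pd.DataFrame(
        rows, columns=["gene", "term", "score", "source", "family", "library"]
    )
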