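"""Merging the two predictors into meta-predictions and filtering them.

Where the learning-based and family-membership predictors agree on a
(gene, term) pair with probabilities p1 and p2, the combined probability is
min(p1 + p2, 1) — agreement between the two routes upweights a term;
single-source predictions pass through at their own probability. The
high-confidence set applies, in order, a strict score filter (> 0.7), a
taxon-constraint ban list, and a strict information-content filter (IC > 5),
and the surviving predictions are partitioned by novelty against a curated
reference annotation set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ontology import (
    HIERARCHY_RELATIONS,
    GeneAnnotationSet,
    OntologyGraph,
    taxon_constrain,
)

logger = logging.getLogger(__name__)

NOVELTY_CLASSES = (
    "obsolete",
    "identical",
    "redundant",
    "novel_deeper",
    "novel_new_subtree",
)


class CombineError(ValueError):
    pass


def combine(nethom: pd.DataFrame, cathpredict: pd.DataFrame) -> pd.DataFrame:
    """min(p1 + p2, 1) on shared (gene, term) rows; pass-through otherwise.

    Inputs are prediction tables with columns (gene, term, score, ...);
    duplicate (gene, term) rows within one source are an error. Output rows
    carry source='netff'. Commutative in its two inputs.
    """
    for name, df in (("nethom", nethom), ("cathpredict", cathpredict)):
        dup = df.duplicated(subset=["gene", "term"])
        if dup.any():
            raise CombineError(f"duplicate (gene, term) rows in {name} input")
    a = nethom[["gene", "term", "score"]].rename(columns={"score": "p1"})
    b = cathpredict[["gene", "term", "score"]].rename(columns={"score": "p2"})
    merged = a.merge(b, on=["gene", "term"], how="outer")
    p1, p2 = merged["p1"].fillna(0.0), merged["p2"].fillna(0.0)
    merged["score"] = np.minimum(p1 + p2, 1.0)
    merged["source"] = "netff"
    extra_cols = [c for c in ("namespace",) if c in nethom.columns or c in cathpredict.columns]
    for c in extra_cols:
        lookup: dict[tuple[str, str], object] = {}
        for df in (nethom, cathpredict):
            if c in df.columns:
                lookup.update({(g, t): v for g, t, v in df[["gene", "term", c]].itertuples(index=False)})
        merged[c] = [lookup.get((g, t)) for g, t in merged[["gene", "term"]].itertuples(index=False)]
    out = merged[["gene", "term", "score", "source", "p1", "p2", *extra_cols]]
    return out.sort_values(["gene", "term"], ignore_index=True)


def filter_high_confidence(
    preds: pd.DataFrame,
    score_min: float = 0.7,
    ic_min: float = 5.0,
    banned_terms=(),
    graph: OntologyGraph | None = None,
    ban_descendants: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Strict score > score_min, then taxon ban, then strict IC > ic_min.

    The filter order is fixed so the logged per-stage survivor counts are
    comparable across runs. Requires an ``IC`` column (see
    :func:`phenofun.ontology.ic_for_new_terms`). Returns the surviving table
    and the per-stage counts.
    """
    if "IC" not in preds.columns:
        raise CombineError("predictions lack an IC column; attach IC first")
    counts = {"input": len(preds)}
    out = preds.loc[preds["score"] > score_min]
    counts["after_score"] = len(out)
    out = taxon_constrain(out, banned_terms, graph=graph, include_descendants=ban_descendants)
    counts["after_taxon"] = len(out)
    out = out.loc[out["IC"] > ic_min].reset_index(drop=True)
    counts["after_ic"] = len(out)
    logger.info("high-confidence filter: %s", counts)
    return out, counts


def partition_novelty(
    preds: pd.DataFrame,
    reference: GeneAnnotationSet,
    graph: OntologyGraph,
    relations: frozenset = HIERARCHY_RELATIONS,
) -> pd.DataFrame:
    """Label each prediction by its relation to the curated reference.

    Classes (exhaustive, mutually exclusive, in precedence order):

    - ``obsolete``: the predicted term is obsolete in the ontology.
    - ``identical``: the term is annotated to the gene in the reference.
    - ``redundant``: a strict descendant of the term is annotated to the
      gene — the prediction only restates an annotation at lower depth
      (the up-propagated case).
    - ``novel_deeper``: the term is a strict descendant of an annotated
      term — a more informative call on an annotated branch.
    - ``novel_new_subtree``: no ancestry relation with the gene's reference
      terms beyond the namespace root.

    Ancestry uses is_a/part_of within the term's namespace. ``reference``
    should be the raw curated set (not up-propagated), otherwise the
    ``redundant`` class absorbs all ancestors by construction.
    """
    ref_sets = {g: reference.term_set(g) for g in reference.genes}
    anc_cache: dict[str, set[str]] = {}

    def ancestors(t: str) -> set[str]:
        if t not in anc_cache:
            anc_cache[t] = graph.ancestors(t, relations)
        return anc_cache[t]

    labels = []
    for gene, term in preds[["gene", "term"]].itertuples(index=False):
        if term not in graph:
            labels.append("novel_new_subtree")
            continue
        if graph.is_obsolete(term):
            labels.append("obsolete")
            continue
        ref = ref_sets.get(gene, set())
        if term in ref:
            labels.append("identical")
        elif any(term in ancestors(r) for r in ref if r in graph):
            labels.append("redundant")
        elif any(r in ancestors(term) for r in ref):
            labels.append("novel_deeper")
        else:
            labels.append("novel_new_subtree")
    out = preds.copy()
    out["novelty"] = labels
    return out
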