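"""One-vs-rest random forests predicting GO terms from gene features.

Targets are GO terms (a slim list or a per-term positive-count window over
up-propagated annotations); one entropy-criterion forest is trained per term
on concatenated embedding + family features, scored by out-of-fold
predictions under repeated stratified cross-validation and summarized as
average precision (AUPR). Hyperparameters (max_features x partial sampling)
are chosen by exhaustive grid search on inner folds only.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

from .ontology import GeneAnnotationSet, OntologyGraph, up_propagate

logger = logging.getLogger(__name__)

MAX_FEATURES_GRID = (10, 25, 50, "sqrt_n")
SAMPLING_GRID = (0.50, 0.75, 1.00)


def _seed32(x: int) -> int:
    """Derived seeds stay inside the 32-bit range scikit-learn accepts."""
    return int(x) % (2**31 - 1)


@dataclass
class TargetMatrix:
    genes: list[str]
    terms: list[str]
    labels: np.ndarray  # genes x terms, {0,1}
    rule: str = ""

    def prevalence(self) -> np.ndarray:
        return self.labels.mean(axis=0)


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters.

    ``partial_sampling`` is the fraction of examples drawn (bootstrap) for
    each tree; ``max_features`` is an integer or the symbolic ``"sqrt_n"``.
    Entropy splitting, min 2 samples to split, no depth cap.
    """

    n_trees: int = 500
    max_features: int | str = "sqrt_n"
    partial_sampling: float = 1.0
    seed: int = 0

    def resolve_max_features(self, n_features: int) -> int:
        if self.max_features == "sqrt_n":
            return max(1, math.floor(math.sqrt(n_features)))
        return max(1, min(int(self.max_features), n_features))


def select_targets(
    annotations: GeneAnnotationSet,
    graph: OntologyGraph,
    mode: str = "range",
    lo: int = 50,
    hi: int = 1000,
    slim_terms: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    namespace: str | None = None,
) -> TargetMatrix:
    """Build the binary gene x term target matrix.

    Annotations are up-propagated before counting, so a gene annotated only
    at a leaf counts toward every ancestor target. ``range`` mode keeps terms
    with a positive count in [lo, hi] inclusive; ``goslim`` keeps the given
    slim list (terms with zero positives dropped).
    """
    closed = up_propagate(annotations, graph)
    gene_list = sorted(genes) if genes is not None else closed.genes
    sets = {g: closed.term_set(g) if g in closed else set() for g in gene_list}
    counts: dict[str, int] = {}
    for s in sets.values():
        for t in s:
            if namespace is None or graph.namespace(t) == namespace:
                counts[t] = counts.get(t, 0) + 1
    if mode == "goslim":
        if not slim_terms:
            raise ValueError("goslim mode needs a slim term list")
        terms = [t for t in slim_terms if counts.get(t, 0) >= 1]
        rule = f"goslim({len(slim_terms)})"
    elif mode == "range":
        terms = sorted(t for t, c in counts.items() if lo <= c <= hi)
        rule = f"range[{lo},{hi}]"
    else:
        raise ValueError(f"unknown target mode: {mode}")
    if not terms:
        raise ValueError("no targets survive selection")
    labels = np.zeros((len(gene_list), len(terms)), dtype=np.int8)
    ti = {t: j for j, t in enumerate(terms)}
    for i, g in enumerate(gene_list):
        for t in sets[g]:
            if t in ti:
                labels[i, ti[t]] = 1
    return TargetMatrix(genes=gene_list, terms=terms, labels=labels, rule=rule)


def _make_forest(config: ForestConfig, n_features: int, seed: int) -> RandomForestClassifier:
    max_samples = None if config.partial_sampling >= 1.0 else config.partial_sampling
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="entropy",
        max_features=config.resolve_max_features(n_features),
        min_samples_split=2,
        max_depth=None,
        bootstrap=True,
        max_samples=max_samples,
        random_state=seed,
        n_jobs=1,
    )


class OvrModel:
    """One fitted forest per target term (None where training was skipped)."""

    def __init__(self, forests, terms, term_columns):
        self.forests = forests
        self.terms = terms
        self.term_columns = term_columns

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros((X.shape[0], len(self.terms)))
        for j, forest in enumerate(self.forests):
            if forest is None:
                continue
            cols = self.term_columns[j]
            Xj = X if cols is None else X[:, cols]
            proba = forest.predict_proba(Xj)
            out[:, j] = proba[:, list(forest.classes_).index(1)] if proba.shape[1] == 2 else forest.classes_[0]
        return out


def family_column_mask(
    n_embedding: int,
    families: Sequence[str],
    membership: Mapping[str, Sequence[str]],
    annotations: GeneAnnotationSet,
    graph: OntologyGraph,
    terms: Sequence[str],
) -> dict[str, np.ndarray]:
    """Per-term usable feature columns when family features are appended.

    For target term g, family columns are restricted to families containing
    at least one protein annotated (after up-propagation) with g; embedding
    columns are always kept. Returns term -> column-index array over the
    concatenated [embedding | family] feature matrix.
    """
    closed = up_propagate(annotations, graph)
    masks: dict[str, np.ndarray] = {}
    fam_terms = {
        f: set().union(*(closed.term_set(m) if m in closed else set() for m in members))
        for f, members in membership.items()
    }
    for t in terms:
        keep = [j for j, f in enumerate(families) if t in fam_terms.get(f, set())]
        cols = list(range(n_embedding)) + [n_embedding + j for j in keep]
        masks[t] = np.asarray(cols, dtype=int)
    return masks


def train_ovr(
    X: np.ndarray,
    targets: TargetMatrix,
    config: ForestConfig,
    term_masks: Mapping[str, np.ndarray] | None = None,
) -> OvrModel:
    """Fit one forest per target term; terms with <2 positives are skipped."""
    forests, columns = [], []
    for j, term in enumerate(targets.terms):
        y = targets.labels[:, j]
        if y.sum() < 2 or y.sum() > len(y) - 1:
            logger.warning("target %s skipped (%d positives)", term, int(y.sum()))
            forests.append(None)
            columns.append(None)
            continue
        cols = None if term_masks is None else term_masks.get(term)
        Xj = X if cols is None else X[:, cols]
        f = _make_forest(config, Xj.shape[1], _seed32(config.seed + j))
        f.fit(Xj, y)
        forests.append(f)
        columns.append(cols)
    return OvrModel(forests, list(targets.terms), columns)


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision; NaN when the labels contain no positive."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        return float("nan")
    return float(average_precision_score(labels, scores))


def macro_aupr(score_matrix: np.ndarray, labels: np.ndarray) -> float:
    vals = [aupr(score_matrix[:, j], labels[:, j]) for j in range(labels.shape[1])]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def micro_aupr(score_matrix: np.ndarray, labels: np.ndarray) -> float:
    return aupr(score_matrix.ravel(), labels.ravel())


def cross_validate(
    X: np.ndarray,
    targets: TargetMatrix,
    config: ForestConfig,
    folds: int = 5,
    trials: int = 5,
    term_masks: Mapping[str, np.ndarray] | None = None,
) -> tuple[dict[int, np.ndarray], pd.DataFrame]:
    """Repeated stratified K-fold out-of-fold scoring, one forest per term.

    Stratification is per target label independently. Returns per-trial
    out-of-fold score matrices and a tidy AUPR table (term, trial, aupr) plus
    macro rows (term='__macro__').
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n, T = targets.labels.shape
    scores: dict[int, np.ndarray] = {}
    rows = []
    for trial in range(trials):
        S = np.zeros((n, T))
        for j, term in enumerate(targets.terms):
            y = targets.labels[:, j]
            if 0 < y.sum() < folds or 0 < (len(y) - y.sum()) < folds:
                logger.warning("target %s: class too small for %d folds; unstratified split", term, folds)
            cols = None if term_masks is None else term_masks.get(term)
            Xj = X if cols is None else X[:, cols]
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=_seed32(config.seed * 1000 + trial))
            try:
                splits = list(skf.split(Xj, y))
            except ValueError:
                # stratification impossible (e.g. a single positive): fall back
                from sklearn.model_selection import KFold

                splits = list(
                    KFold(n_splits=folds, shuffle=True, random_state=_seed32(config.seed * 1000 + trial)).split(Xj)
                )
            for train, test in splits:
                ytr = y[train]
                if ytr.sum() < 2:
                    continue
                f = _make_forest(config, Xj.shape[1], _seed32(config.seed + 7919 * trial + j))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    f.fit(Xj[train], ytr)
                proba = f.predict_proba(Xj[test])
                S[test, j] = proba[:, list(f.classes_).index(1)] if proba.shape[1] == 2 else 0.0
            rows.append((term, trial, aupr(S[:, j], y)))
        rows.append(("__macro__", trial, macro_aupr(S, targets.labels)))
        scores[trial] = S
    report = pd.DataFrame(rows, columns=["term", "trial", "aupr"])
    return scores, report


def grid_search(
    X: np.ndarray,
    targets: TargetMatrix,
    base: ForestConfig | None = None,
    max_features_grid: Sequence = MAX_FEATURES_GRID,
    sampling_grid: Sequence[float] = SAMPLING_GRID,
    inner_folds: int = 5,
    term_masks: Mapping[str, np.ndarray] | None = None,
) -> tuple[ForestConfig, pd.DataFrame]:
    """Exhaustive grid search over (max_features, partial_sampling).

    Each cell is scored by mean macro AUPR over a single stratified
    ``inner_folds``-fold cross-validation of the supplied (training) data.
    Ties break toward smaller resolved max_features, then larger sampling.
    """
    base = base or ForestConfig()
    results = []
    for mf in max_features_grid:
        for ps in sampling_grid:
            cfg = replace(base, max_features=mf, partial_sampling=ps)
            _, report = cross_validate(X, targets, cfg, folds=inner_folds, trials=1, term_masks=term_masks)
            score = float(report.loc[report["term"] == "__macro__", "aupr"].mean())
            results.append((mf, ps, score, cfg))
    table = pd.DataFrame(
        [(mf, ps, sc) for mf, ps, sc, _ in results],
        columns=["max_features", "partial_sampling", "macro_aupr"],
    )
    nf = X.shape[1]
    # scores compared at 1e-9 resolution so float noise cannot defeat the
    # deterministic tie-break (smaller max_features, then larger sampling)
    best = max(results, key=lambda r: (round(r[2], 9), -r[3].resolve_max_features(nf), r[1]))
    return best[3], table
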