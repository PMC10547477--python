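"""Colony-fitness hit calling, ternary discretization and PAM clustering.

Fitness values are colony-size ratios to the wild-type grid on the same
plate. Benign conditions (rich/minimal medium, many repeats) are called with
a two-sided Welch t-test against the wild-type repeats plus a
Benjamini-Hochberg correction across strains within each condition
(hit: adjusted p < 0.05 and >= 5% median fitness difference). Stress
conditions (few repeats) use only a 10% effect rule on the control-normalized
phenotype score. Scores are discretized to -1/0/+1 at the +/-10% bands,
filtered, and mutants are clustered by k-medoids (PAM, deterministic BUILD +
SWAP) on the 1 - Pearson distance between phenotype profiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class PhenomicsError(ValueError):
    pass


def _median_by(df: pd.DataFrame) -> pd.DataFrame:
    return df.groupby(["strain", "condition"])["fitness"].median().rename("median").reset_index()


def call_benign(
    fitness: pd.DataFrame,
    conditions: list[str] | None = None,
    wt: str = "wildtype",
    alpha: float = 0.05,
    effect: float = 0.05,
) -> pd.DataFrame:
    """Benign-condition hit table.

    ``fitness`` has columns (strain, condition, repeat, fitness). Per strain
    and condition, a two-sided Welch t-test compares the strain's repeats to
    the wild-type repeats in that condition; p-values are BH-adjusted across
    strains within the condition. A hit needs adjusted p < ``alpha`` AND
    |median - 1| >= ``effect``; the sign of median - 1 sets the direction.
    Strains with fewer than 2 repeats are flagged untestable.
    """
    if (fitness["fitness"] <= 0).any():
        raise PhenomicsError("fitness values must be positive")
    conds = conditions if conditions is not None else sorted(fitness["condition"].unique())
    rows = []
    for cond in conds:
        sub = fitness.loc[fitness["condition"] == cond]
        wt_vals = sub.loc[sub["strain"] == wt, "fitness"].to_numpy()
        if len(wt_vals) < 2:
            raise PhenomicsError(f"condition {cond}: need >=2 wild-type repeats")
        strains, pvals, medians, testable = [], [], [], []
        for strain, grp in sub.groupby("strain"):
            if strain == wt:
                continue
            vals = grp["fitness"].to_numpy()
            strains.append(strain)
            medians.append(float(np.median(vals)))
            if len(vals) < 2:
                pvals.append(np.nan)
                testable.append(False)
            else:
                t = stats.ttest_ind(vals, wt_vals, equal_var=False)
                pvals.append(float(t.pvalue) if np.isfinite(t.pvalue) else 1.0)
                testable.append(True)
        pvals = np.asarray(pvals)
        adj = np.full_like(pvals, np.nan)
        ok = np.isfinite(pvals)
        if ok.any():
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        for strain, med, p, padj, t in zip(strains, medians, pvals, adj, testable):
            if not t:
                call = "untestable"
            elif padj < alpha and abs(med - 1.0) >= effect:
                call = "slow" if med < 1.0 else "fast"
            else:
                call = "none"
            rows.append((strain, cond, med, p, padj, call))
    return pd.DataFrame(rows, columns=["strain", "condition", "median", "p", "adj_p", "call"])


def stress_scores(
    fitness: pd.DataFrame,
    condition_map: pd.DataFrame,
    wt: str = "wildtype",
) -> pd.DataFrame:
    """Phenotype score per strain x stress condition.

    ``condition_map`` has columns (condition, control, is_benign). The score
    is (median fitness in the condition) / (median fitness in the mapped
    control medium) — fitness is already wild-type-normalized per plate.
    Strains missing the control measurement get a missing score.
    """
    med = _median_by(fitness).set_index(["strain", "condition"])["median"]
    rows = []
    stress = condition_map.loc[~condition_map["is_benign"].astype(bool)]
    for cond, control in stress[["condition", "control"]].itertuples(index=False):
        for strain in sorted(fitness["strain"].unique()):
            if strain == wt:
                continue
            num = med.get((strain, cond), np.nan)
            den = med.get((strain, control), np.nan)
            score = num / den if np.isfinite(num) and np.isfinite(den) and den > 0 else np.nan
            rows.append((strain, cond, score))
    return pd.DataFrame(rows, columns=["strain", "condition", "score"])


def call_stress(
    fitness: pd.DataFrame,
    condition_map: pd.DataFrame,
    wt: str = "wildtype",
    effect: float = 0.10,
) -> pd.DataFrame:
    """Stress-condition hit table: |score - 1| >= ``effect``; no p-values."""
    scores = stress_scores(fitness, condition_map, wt=wt)

    def classify(s: float) -> str:
        if not np.isfinite(s):
            return "missing"
        if s <= 1.0 - effect:
            return "sensitive"
        if s >= 1.0 + effect:
            return "resistant"
        return "none"

    scores["call"] = [classify(s) for s in scores["score"]]
    return scores


def discretize(
    scores: pd.DataFrame,
    benign_hits: pd.DataFrame | None = None,
    effect: float = 0.10,
    alpha: float = 0.05,
    benign_effect: float | None = None,
) -> pd.DataFrame:
    """Ternary strains x conditions matrix.

    ``scores`` is tidy (strain, condition, score). A score <= 1 - ``effect``
    codes -1, >= 1 + ``effect`` codes +1, otherwise 0 (boundaries inclusive).
    For benign conditions pass ``benign_hits`` (from :func:`call_benign`):
    their medians are the scores and, additionally, entries are zeroed unless
    adjusted p < ``alpha``. Missing scores stay NaN.
    """
    frames = [scores[["strain", "condition", "score"]].copy()]
    gates = {}
    if benign_hits is not None:
        b = benign_hits.rename(columns={"median": "score"})[["strain", "condition", "score"]].copy()
        frames.append(b)
        for strain, cond, padj in benign_hits[["strain", "condition", "adj_p"]].itertuples(index=False):
            gates[(strain, cond)] = bool(np.isfinite(padj) and padj < alpha)
    tidy = pd.concat(frames, ignore_index=True)
    be = benign_effect if benign_effect is not None else effect

    def code(strain, cond, s):
        if not np.isfinite(s):
            return np.nan
        benign = (strain, cond) in gates
        eff = be if benign else effect
        if benign and not gates[(strain, cond)]:
            return 0.0
        if s <= 1.0 - eff:
            return -1.0
        if s >= 1.0 + eff:
            return 1.0
        return 0.0

    tidy["code"] = [code(st, c, s) for st, c, s in tidy[["strain", "condition", "score"]].itertuples(index=False)]
    tidy = tidy.drop_duplicates(subset=["strain", "condition"], keep="first")
    return tidy.pivot(index="strain", columns="condition", values="code")


def filter_matrix(matrix: pd.DataFrame, mode: str = "methods") -> pd.DataFrame:
    """Row/column filtering of the ternary matrix.

    ``methods`` mode drops strains with >50% missing values and conditions
    with >90% zero scores. ``fig3`` mode drops strains and conditions with
    fewer than 4 phenotypes (nonzero entries, both signs counted), the
    conditions with more than 2400 phenotypes, and strains with >50% missing
    values.
    """
    m = matrix.copy()
    log: list[str] = []
    if mode == "methods":
        frac_missing = m.isna().mean(axis=1)
        drop_rows = m.index[frac_missing > 0.5]
        m = m.drop(index=drop_rows)
        zero_frac = (m == 0).sum(axis=0) / m.notna().sum(axis=0)
        drop_cols = m.columns[zero_frac > 0.9]
        m = m.drop(columns=drop_cols)
        log.append(f"dropped {len(drop_rows)} strains (>50% missing), {len(drop_cols)} conditions (>90% zeros)")
    elif mode == "fig3":
        nz_col = (m.fillna(0) != 0).sum(axis=0)
        drop_cols = m.columns[(nz_col < 4) | (nz_col > 2400)]
        m = m.drop(columns=drop_cols)
        nz_row = (m.fillna(0) != 0).sum(axis=1)
        frac_missing = m.isna().mean(axis=1)
        drop_rows = m.index[(nz_row < 4) | (frac_missing > 0.5)]
        m = m.drop(index=drop_rows)
        log.append(f"dropped {len(drop_cols)} conditions, {len(drop_rows)} strains")
    else:
        raise ValueError(f"unknown filter mode: {mode}")
    if m.empty:
        raise PhenomicsError("filtering removed every row")
    logger.info("filter_matrix(%s): %s", mode, "; ".join(log))
    return m


def correlation_distance(
    matrix: pd.DataFrame, min_overlap: int = 20
) -> np.ndarray:
    """1 - Pearson distance between rows, pairwise-complete.

    Pairs sharing fewer than ``min_overlap`` non-missing conditions, and rows
    of zero variance, get a missing distance imputed as the median observed
    distance (diagonal 0 always).
    """
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.full((n, n), np.nan)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(i + 1, n):
            ok = np.isfinite(x[i]) & np.isfinite(x[j])
            if ok.sum() < min_overlap:
                continue
            xi, xj = x[i, ok], x[j, ok]
            if np.std(xi) == 0 or np.std(xj) == 0:
                d[i, j] = d[j, i] = 1.0  # correlation undefined: maximally dissimilar
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            d[i, j] = d[j, i] = 1.0 - r
    off = d[~np.eye(n, dtype=bool)]
    if np.isnan(off).all():
        raise PhenomicsError(
            f"no strain pair shares >= {min_overlap} conditions; lower min_overlap"
        )
    if np.isnan(off).any():
        med = float(np.nanmedian(off))
        n_miss = int(np.isnan(off).sum() // 2)
        logger.info("imputing %d missing pairwise distances with median %.3f", n_miss, med)
        d = np.where(np.isnan(d), med, d)
    return d


def _pam_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def pam(d: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, list[int], float]:
    """Partitioning around medoids: deterministic BUILD then SWAP.

    BUILD seeds with the point of minimum total distance and greedily adds
    the medoid giving the largest cost reduction; SWAP applies the best
    improving (medoid, non-medoid) exchange until none improves. The total
    cost is non-increasing across iterations. Ties break on lowest index.
    """
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        best_gain, best_c = -np.inf, None
        for c in range(n):
            if c in medoids:
                continue
            gain = float(np.maximum(nearest - d[:, c], 0).sum())
            if gain > best_gain:
                best_gain, best_c = gain, c
        medoids.append(best_c)
    cost = _pam_cost(d, medoids)
    for _ in range(max_iter):
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for c in range(n):
                if c in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = c
                delta = cost - _pam_cost(d, trial)
                if delta > best[0] + 1e-12:
                    best = (delta, mi, c)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        new_cost = _pam_cost(d, medoids)
        assert new_cost <= cost + 1e-9
        cost = new_cost
    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1)
    return labels, medoids, cost


def silhouette(d: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(d, labels, metric="precomputed"))


def pam_cluster(
    matrix: pd.DataFrame,
    k: int | None = None,
    k_range: range = range(2, 13),
    min_overlap: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster strains by PAM on the 1 - Pearson profile distance.

    With ``k`` given, clusters at that k; otherwise k is chosen from
    ``k_range`` by maximum mean silhouette. Returns a table (strain, cluster,
    medoid, k, silhouette). The procedure is deterministic; ``seed`` is kept
    for interface symmetry only.
    """
    d = correlation_distance(matrix, min_overlap=min_overlap)
    n = d.shape[0]
    if k is not None:
        labels, medoids, _ = pam(d, k)
        sil = silhouette(d, labels) if 1 < k < n else float("nan")
    else:
        best = None
        for kk in k_range:
            if not 2 <= kk < n:
                continue
            labels_k, medoids_k, _ = pam(d, kk)
            if len(set(labels_k.tolist())) < 2:
                continue
            s = silhouette(d, labels_k)
            if best is None or s > best[0]:
                best = (s, kk, labels_k, medoids_k)
        if best is None:
            raise PhenomicsError("no k in range yields >=2 clusters")
        sil, k, labels, medoids = best
    strains = list(matrix.index)
    return pd.DataFrame(
        {
            "strain": strains,
            "cluster": labels.astype(int),
            "medoid": [strains[medoids[l]] for l in labels],
            "k": k,
            "silhouette": sil,
        }
    )
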