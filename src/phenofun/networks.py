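"""Phenotype-correlation networks and their integration with GO similarity.

The PHEPHE score of a gene pair is the Pearson correlation of their
phenotype profiles across conditions (two-sided t-transform p-values,
BH-adjusted across all pairs). Networks keep edges with |r| > 0.7 and
adjusted p < 0.01, signed; clusters come from greedy modularity communities
within connected components. The integration rule joins the two evidence
routes: a gene pair enters the combined network iff its GO-similarity (BP)
score exceeds 0.5 AND the product GO-similarity x PHEPHE exceeds 0.5, which
a label-permuted control network calibrates against chance.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def phephe(profiles: pd.DataFrame, min_overlap: int = 20) -> pd.DataFrame:
    """Pairwise profile-correlation table.

    ``profiles`` is strains x conditions (continuous phenotype scores by
    default; a ternary matrix works identically). Pairs with fewer than
    ``min_overlap`` shared non-missing conditions are omitted. Returns
    (geneA, geneB, r, n, p, adj_p, sign) with geneA < geneB.
    """
    x = profiles.to_numpy(dtype=float)
    genes = list(profiles.index)
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            ok = np.isfinite(x[i]) & np.isfinite(x[j])
            n = int(ok.sum())
            if n < min_overlap:
                continue
            xi, xj = x[i, ok], x[j, ok]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            r = max(-1.0, min(1.0, r))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            a, b = sorted((genes[i], genes[j]))
            rows.append((a, b, r, n, p))
    df = pd.DataFrame(rows, columns=["geneA", "geneB", "r", "n", "p"])
    if len(df):
        df["adj_p"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["adj_p"] = pd.Series(dtype=float)
    df["sign"] = np.sign(df["r"]).astype(int)
    return df


def build_network(edges: pd.DataFrame, rmin: float = 0.7, pmax: float = 0.01) -> nx.Graph:
    """Graph of edges with |r| > ``rmin`` (strict) and adjusted p < ``pmax``."""
    g = nx.Graph()
    if len(edges) == 0:
        return g
    keep = edges.loc[(edges["r"].abs() > rmin) & (edges["adj_p"] < pmax)]
    for row in keep.itertuples(index=False):
        g.add_edge(row.geneA, row.geneB, r=float(row.r), sign=int(np.sign(row.r)),
                   adj_p=float(row.adj_p))
    return g


def community_clusters(graph: nx.Graph, seed: int = 0) -> dict[str, int]:
    """Greedy-modularity communities within each connected component.

    Deterministic: components and communities are processed in sorted order;
    singleton components become singleton clusters. Returns node -> cluster id.
    """
    assignment: dict[str, int] = {}
    next_id = 0
    for comp in sorted(nx.connected_components(graph), key=lambda c: (-len(c), sorted(c)[0])):
        sub = graph.subgraph(comp)
        if len(comp) == 1 or sub.number_of_edges() == 0:
            for node in sorted(comp):
                assignment[node] = next_id
                next_id += 1
            continue
        comms = nx.community.greedy_modularity_communities(sub)
        for comm in sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0])):
            for node in comm:
                assignment[node] = next_id
            next_id += 1
    return assignment


def _canonical_pairs(df: pd.DataFrame, score_col: str) -> pd.DataFrame:
    a = df["geneA"].astype(str)
    b = df["geneB"].astype(str)
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return pd.DataFrame({"geneA": lo, "geneB": hi, score_col: df[score_col].to_numpy()})


def integrate_gogo_phephe(
    gogo: pd.DataFrame,
    phephe_table: pd.DataFrame,
    gate: float = 0.5,
    product_gate: float = 0.5,
) -> pd.DataFrame:
    """Gene pairs with GOGO_BP > ``gate`` and GOGO_BP x PHEPHE > ``product_gate``.

    ``gogo`` needs columns (geneA, geneB, score); ``phephe_table`` needs
    (geneA, geneB, r). Pairs present in only one table are skipped (count
    logged). Negative-correlation pairs cannot pass the product gate.
    Returns (geneA, geneB, GOGO_BP, PHEPHE, product).
    """
    g = _canonical_pairs(gogo.rename(columns={"score": "GOGO_BP"}), "GOGO_BP")
    p = _canonical_pairs(phephe_table.rename(columns={"r": "PHEPHE"}), "PHEPHE")
    merged = g.merge(p, on=["geneA", "geneB"], how="outer", indicator=True)
    n_unmatched = int((merged["_merge"] != "both").sum())
    if n_unmatched:
        logger.info("integration skipped %d pairs present in only one table", n_unmatched)
    both = merged.loc[merged["_merge"] == "both"].drop(columns="_merge").copy()
    both["product"] = both["GOGO_BP"] * both["PHEPHE"]
    out = both.loc[(both["GOGO_BP"] > gate) & (both["product"] > product_gate)]
    return out.reset_index(drop=True)


def random_control_network(
    gogo: pd.DataFrame,
    phephe_table: pd.DataFrame,
    seed: int,
    gate: float = 0.5,
    product_gate: float = 0.5,
) -> pd.DataFrame:
    """Label-permuted null for the integration network.

    Gene labels of the PHEPHE table are permuted (seeded) before applying
    the same two gates, preserving both marginal score distributions.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(set(phephe_table["geneA"]).union(phephe_table["geneB"]))
    mapping = dict(zip(genes, rng.permutation(genes)))
    shuffled = phephe_table.copy()
    shuffled["geneA"] = shuffled["geneA"].map(mapping)
    shuffled["geneB"] = shuffled["geneB"].map(mapping)
    return integrate_gogo_phephe(gogo, shuffled, gate=gate, product_gate=product_gate)


def overlap_permutation_test(
    pairs_a: set[tuple[str, str]],
    pairs_b: set[tuple[str, str]],
    genes: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[int, float]:
    """Observed overlap of two pair sets vs a gene-label permutation null.

    Returns (observed overlap, one-sided p-value for enrichment). Used to
    check that e.g. high-correlation pairs overlap a known-interaction list
    more than chance.
    """
    def canon(pairs):
        return {tuple(sorted(p)) for p in pairs}

    pa, pb = canon(pairs_a), canon(pairs_b)
    observed = len(pa & pb)
    rng = np.random.default_rng(seed)
    count = 0
    genes = list(genes)
    for _ in range(n_perm):
        mapping = dict(zip(genes, rng.permutation(genes)))
        shuffled = {tuple(sorted((mapping[a], mapping[b]))) for a, b in pa}
        if len(shuffled & pb) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return observed, p


def export_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
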