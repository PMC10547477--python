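"""Seeded synthetic inputs with planted ground truth for every stage.

One :class:`FixtureSpec` plus a seed fully determines a miniature study: a
random GO-style DAG per namespace with module-specific deep subtrees, gene
annotations drawn from those subtrees (so module-mates share specific
terms), six stochastic-block-model network layers over the same modules,
protein families nested within modules with exactly constructed
member-annotation proportions, and replicate colony-fitness tables with
planted hits and module-shared condition-response archetypes. Defaults are
sized for desk-scale runs (~100-200 genes, ~200 terms, ~25 conditions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import LAYER_NAMES, NetworkStack, build_stack
from .funfam import DomainHit
from .ontology import GeneAnnotationSet, OntologyGraph, TermInfo

_SUBSEED = {"ontology": 11, "networks": 23, "families": 37, "phenotypes": 53, "ternary": 71}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _SUBSEED[stream]]))


@dataclass
class FixtureSpec:
    seed: int = 1
    # ontology
    n_terms_bp: int = 120
    n_terms_mf: int = 60
    part_of_prob: float = 0.25
    second_parent_prob: float = 0.3
    # genes / modules
    n_genes: int = 100
    n_modules: int = 5
    terms_per_gene: tuple[int, int] = (3, 6)
    annotation_noise: float = 0.1
    # networks (six layers)
    p_within: float = 0.3
    p_between: float = 0.02
    # families
    n_families: int = 15
    family_size: tuple[int, int] = (3, 6)
    # phenotypes
    n_benign: int = 2
    n_stress: int = 22
    repeats_benign: int = 10
    repeats_stress: int = 4
    effect: float = 0.25          # fitness multiplier shift of a planted hit
    benign_effect: float = 0.10   # shift of planted benign hits
    hit_fraction: float = 0.15    # fraction of strain x stress cells with a true effect
    noise_sd: float = 0.03        # multiplicative lognormal noise
    ternary_flip: float = 0.05    # flip rate for direct ternary archetype fixtures
    n_ternary_conditions: int = 30

    def genes(self) -> list[str]:
        return [f"gene{i:03d}" for i in range(self.n_genes)]

    def modules(self) -> dict[str, int]:
        return {g: i % self.n_modules for i, g in enumerate(self.genes())}


def _make_namespace(
    rng: np.random.Generator,
    prefix: int,
    n_terms: int,
    namespace: str,
    n_modules: int,
    spec: FixtureSpec,
) -> tuple[dict[str, TermInfo], list[tuple[str, str, str]], dict[int, list[str]]]:
    """Random DAG: a general backbone plus one deep chain-like subtree per module.

    Every term keeps at least one is_a parent path to the namespace root.
    Returns (terms, edges, module term pools).
    """
    ids = [f"GO:{prefix:02d}{i:05d}" for i in range(n_terms)]
    terms = {t: TermInfo(name=f"{namespace} term {i}", namespace=namespace) for i, t in enumerate(ids)}
    edges: list[tuple[str, str, str]] = []
    n_backbone = max(n_modules + 1, int(0.4 * n_terms))
    depth = {ids[0]: 0}
    for i in range(1, n_backbone):
        # bias toward recent terms for depth
        j = int(rng.integers(max(0, i - 8), i))
        edges.append((ids[i], ids[j], "is_a"))
        depth[ids[i]] = depth[ids[j]] + 1
        if rng.random() < spec.second_parent_prob and i > 1:
            k = int(rng.integers(0, i))
            if k != j:
                rel = "part_of" if rng.random() < spec.part_of_prob else "is_a"
                edges.append((ids[i], ids[k], rel))
    # module subtrees hang off distinct deep backbone terms
    pool_terms = ids[n_backbone:]
    per_module = len(pool_terms) // n_modules if n_modules else 0
    deep_backbone = sorted(range(1, n_backbone), key=lambda i: -depth[ids[i]])
    pools: dict[int, list[str]] = {m: [] for m in range(n_modules)}
    for m in range(n_modules):
        anchor = ids[deep_backbone[m % len(deep_backbone)]]
        members = pool_terms[m * per_module : (m + 1) * per_module]
        prev = anchor
        for idx, t in enumerate(members):
            parent = prev if idx == 0 or rng.random() < 0.7 else members[int(rng.integers(0, idx))]
            edges.append((t, parent, "is_a"))
            if rng.random() < spec.part_of_prob and idx > 0:
                extra = members[int(rng.integers(0, idx))]
                if extra != parent:
                    edges.append((t, extra, "part_of"))
            prev = t
            pools[m].append(t)
    # leftovers join the backbone
    for t in pool_terms[n_modules * per_module :]:
        j = int(rng.integers(0, n_backbone))
        edges.append((t, ids[j], "is_a"))
    return terms, edges, pools


def make_ontology(spec: FixtureSpec) -> tuple[OntologyGraph, GeneAnnotationSet, dict]:
    """Ontology + gene annotations with module-shared deep terms.

    Each gene draws most of its BP terms from its module's subtree pool and
    1-2 MF terms from the module's MF pool; with probability
    ``annotation_noise`` a record lands on a random term instead. Truth dict
    carries the module assignment and the per-module term pools.
    """
    rng = _rng(spec.seed, "ontology")
    bp_terms, bp_edges, bp_pools = _make_namespace(rng, 10, spec.n_terms_bp, "BP", spec.n_modules, spec)
    mf_terms, mf_edges, mf_pools = _make_namespace(rng, 20, spec.n_terms_mf, "MF", spec.n_modules, spec)
    graph = OntologyGraph({**bp_terms, **mf_terms}, bp_edges + mf_edges)
    all_bp, all_mf = list(bp_terms), list(mf_terms)
    annotations = GeneAnnotationSet()
    modules = spec.modules()
    evidences = ["IDA", "IMP", "IGI", "EXP"]
    for gene in spec.genes():
        m = modules[gene]
        k = int(rng.integers(spec.terms_per_gene[0], spec.terms_per_gene[1] + 1))
        pool = bp_pools[m]
        for _ in range(k):
            if pool and rng.random() >= spec.annotation_noise:
                t = pool[int(rng.integers(0, len(pool)))]
            else:
                t = all_bp[int(rng.integers(1, len(all_bp)))]
            annotations.add(gene, t, evidences[int(rng.integers(0, len(evidences)))])
        for _ in range(int(rng.integers(1, 3))):
            mf_pool = mf_pools[m]
            if mf_pool and rng.random() >= spec.annotation_noise:
                t = mf_pool[int(rng.integers(0, len(mf_pool)))]
            else:
                t = all_mf[int(rng.integers(1, len(all_mf)))]
            annotations.add(gene, t, evidences[int(rng.integers(0, len(evidences)))])
    truth = {"modules": modules, "bp_pools": bp_pools, "mf_pools": mf_pools}
    return graph, annotations, truth


def make_networks(spec: FixtureSpec) -> tuple[dict[str, pd.DataFrame], NetworkStack]:
    """Six stochastic-block-model layers sharing the module structure.

    Each layer gets its own sub-seed and a mild jitter on the within-module
    edge probability; edge weights are uniform(0.3, 1).
    """
    rng = _rng(spec.seed, "networks")
    genes = spec.genes()
    modules = spec.modules()
    edge_lists: dict[str, pd.DataFrame] = {}
    for name in LAYER_NAMES:
        p_within = spec.p_within * float(rng.uniform(0.8, 1.2))
        rows = []
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                same = modules[genes[i]] == modules[genes[j]]
                p = p_within if same else spec.p_between
                if rng.random() < p:
                    rows.append((genes[i], genes[j], float(rng.uniform(0.3, 1.0))))
        edge_lists[name] = pd.DataFrame(rows, columns=["geneA", "geneB", "weight"])
    return edge_lists, build_stack(edge_lists, genes)


def make_families(
    spec: FixtureSpec,
    annotations: GeneAnnotationSet,
    truth: dict,
) -> tuple[dict[str, list[str]], list[DomainHit], dict[str, list[str]], list[DomainHit], dict]:
    """Protein families nested within modules, plus domain hit tables.

    Families draw members from a single module, so member-annotation
    proportions follow from the actual fixture annotations (exactly
    recomputable). Two-thirds of the families form the primary (cath-style)
    library; the rest form the fallback (pfam-style) library whose member
    proteins get no primary hits, exercising the fallback branch. Hit
    E-values are log-uniform in [1e-30, 1e-5] for true members, with decoy
    hits above the significance threshold sprinkled in.
    """
    rng = _rng(spec.seed, "families")
    genes = spec.genes()
    modules = truth["modules"]
    by_module: dict[int, list[str]] = {}
    for g in genes:
        by_module.setdefault(modules[g], []).append(g)
    n_cath = max(1, (2 * spec.n_families) // 3)
    cath_membership: dict[str, list[str]] = {}
    pfam_membership: dict[str, list[str]] = {}
    pfam_only: set[str] = set()
    for fi in range(spec.n_families):
        m = fi % spec.n_modules
        size = int(rng.integers(spec.family_size[0], spec.family_size[1] + 1))
        members = list(rng.choice(by_module[m], size=min(size, len(by_module[m])), replace=False))
        if fi < n_cath:
            cath_membership[f"FF{fi:04d}"] = sorted(members)
        else:
            pfam_membership[f"PF{fi:04d}"] = sorted(members)
            pfam_only.update(members)
    # proteins in cath families must not be pfam-only
    cath_proteins = {p for mem in cath_membership.values() for p in mem}
    pfam_only -= cath_proteins

    def hits_for(membership: dict[str, list[str]], source: str) -> list[DomainHit]:
        out = []
        for fam, members in sorted(membership.items()):
            for p in members:
                if source == "cath" and p in pfam_only:
                    continue
                e = 10.0 ** float(rng.uniform(-30, -5))
                bit = 25.0 + 4.0 * (-np.log10(e)) + float(rng.uniform(0, 5))
                start = int(rng.integers(1, 300))
                stop = start + int(rng.integers(40, 200))
                out.append(DomainHit(p, fam, e, bit, start, stop, source))
                if rng.random() < 0.15:  # insignificant decoy, must be filtered out
                    e2 = 10.0 ** float(rng.uniform(-2.9, -1))
                    out.append(DomainHit(p, fam, e2, 12.0 + float(rng.uniform(0, 6)), start, stop, source))
        return out

    cath_hits = hits_for(cath_membership, "cath")
    pfam_hits = hits_for(pfam_membership, "pfam")
    fam_truth = {"pfam_only_proteins": sorted(pfam_only)}
    return cath_membership, cath_hits, pfam_membership, pfam_hits, fam_truth


def make_phenotypes(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Replicate colony-fitness table with planted hits and archetypes.

    Conditions: ``benign0..`` (control media, many repeats) and
    ``stress0..`` each mapped to benign0 as its control. Per module an
    archetype assigns each stress condition an effect in {-, 0, +} (nonzero
    with probability ``hit_fraction``, split evenly); a strain's fitness in a
    condition is its archetype multiplier (1, 1-effect or 1+effect) under
    multiplicative lognormal noise. Benign hits are planted per strain with
    probability 0.1 at ``benign_effect``. Wild-type fitness is 1 with noise.
    Truth: per-cell hit directions and the module (cluster) labels.
    """
    rng = _rng(spec.seed, "phenotypes")
    genes = spec.genes()
    modules = spec.modules()
    benign = [f"benign{i}" for i in range(spec.n_benign)]
    stress = [f"stress{i}" for i in range(spec.n_stress)]
    cmap = pd.DataFrame(
        [(c, c, True) for c in benign] + [(c, benign[0], False) for c in stress],
        columns=["condition", "control", "is_benign"],
    )
    archetypes = {}
    for m in range(spec.n_modules):
        eff = np.zeros(spec.n_stress)
        for j in range(spec.n_stress):
            u = rng.random()
            if u < spec.hit_fraction / 2:
                eff[j] = -spec.effect
            elif u < spec.hit_fraction:
                eff[j] = spec.effect
        archetypes[m] = eff
    rows, hit_rows = [], []
    strains = genes + ["wildtype"]
    for strain in strains:
        if strain == "wildtype":
            mult_benign = {c: 1.0 for c in benign}
            mult_stress = np.ones(spec.n_stress)
        else:
            mult_benign = {}
            for c in benign:
                u = rng.random()
                if u < 0.05:
                    mult_benign[c] = 1.0 - spec.benign_effect
                elif u < 0.10:
                    mult_benign[c] = 1.0 + spec.benign_effect
                else:
                    mult_benign[c] = 1.0
            mult_stress = 1.0 + archetypes[modules[strain]]
        for c in benign:
            for rep in range(spec.repeats_benign):
                noise = float(rng.lognormal(0.0, spec.noise_sd))
                rows.append((strain, c, rep, mult_benign[c] * noise))
            if strain != "wildtype":
                direction = int(np.sign(mult_benign[c] - 1.0))
                hit_rows.append((strain, c, direction))
        for j, c in enumerate(stress):
            # a constitutive (benign-medium) fitness defect carries into the
            # stress plates; the control-media normalization cancels it
            base = mult_benign[benign[0]]
            for rep in range(spec.repeats_stress):
                noise = float(rng.lognormal(0.0, spec.noise_sd))
                rows.append((strain, c, rep, base * float(mult_stress[j]) * noise))
            if strain != "wildtype":
                hit_rows.append((strain, c, int(np.sign(mult_stress[j] - 1.0))))
    fitness = pd.DataFrame(rows, columns=["strain", "condition", "repeat", "fitness"])
    hits = pd.DataFrame(hit_rows, columns=["strain", "condition", "direction"])
    clusters = pd.DataFrame(
        {"strain": genes, "module": [modules[g] for g in genes]}
    )
    truth = {"hits": hits, "clusters": clusters, "archetypes": archetypes}
    return fitness, cmap, truth


def make_ternary_archetypes(
    n_strains: int = 60,
    n_archetypes: int = 3,
    n_conditions: int = 30,
    flip: float = 0.05,
    seed: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Direct ternary matrix of planted archetype rows with flip noise.

    Each archetype is a ternary vector (entries -1/0/+1 with probabilities
    0.3/0.4/0.3); each strain copies its archetype and each entry flips to a
    random different value with probability ``flip``. Returns (matrix,
    truth labels).
    """
    rng = _rng(seed, "ternary")
    values = np.array([-1.0, 0.0, 1.0])
    archetypes = rng.choice(values, size=(n_archetypes, n_conditions), p=[0.3, 0.4, 0.3])
    rows, labels = [], []
    for i in range(n_strains):
        a = i % n_archetypes
        row = archetypes[a].copy()
        for j in range(n_conditions):
            if rng.random() < flip:
                row[j] = rng.choice(values[values != row[j]])
        rows.append(row)
        labels.append(a)
    idx = [f"strain{i:03d}" for i in range(n_strains)]
    matrix = pd.DataFrame(rows, index=idx, columns=[f"cond{j:02d}" for j in range(n_conditions)])
    truth = pd.DataFrame({"strain": idx, "archetype": labels})
    return matrix, truth
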