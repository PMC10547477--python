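"""End-to-end orchestration: config, staged execution, manifests.

``run_pipeline`` executes the stages in dependency order — simulate ->
ontology (IC) -> embed -> nethom -> cathpredict -> combine -> gogo ->
pheno -> networks — writing every intermediate as a TSV and a JSON manifest
per stage with input/output hashes. Two runs with the same config and seed
produce byte-identical score tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import combiner, embedding, fixtures, funfam, io, learner, networks, ontology, phenomics, similarity

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "ontology",
    "embed",
    "nethom",
    "cathpredict",
    "combine",
    "gogo",
    "pheno",
    "networks",
)


class PipelineError(RuntimeError):
    pass


def _strict_make(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class EmbedBlock:
    hidden: int = 64
    embedding_dim: int = 32
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 1e-2
    activation: str = "sigmoid"
    preprocess_rwr_ppmi: bool = False


@dataclass
class LearnerBlock:
    n_trees: int = 150
    max_features: int | str = "sqrt_n"
    partial_sampling: float = 1.0
    folds: int = 5
    trials: int = 1
    target_mode: str = "range"
    target_lo: int = 10
    target_hi: int = 80
    namespace: str = "BP"


@dataclass
class CombinerBlock:
    score_min: float = 0.7
    ic_min: float = 5.0
    banned_terms: list = field(default_factory=list)


@dataclass
class PhenomicsBlock:
    alpha: float = 0.05
    benign_effect: float = 0.05
    stress_effect: float = 0.10
    ternary_effect: float = 0.10
    filter_mode: str = "methods"
    k_min: int = 2
    k_max: int = 12
    min_overlap: int = 5  # desk-scale fixtures keep ~10 active conditions


@dataclass
class NetworksBlock:
    rmin: float = 0.7
    pmax: float = 0.01
    gate: float = 0.5
    product_gate: float = 0.5
    min_overlap: int = 20


@dataclass
class RunConfig:
    """Pipeline configuration; unknown keys are rejected.

    Module-level defaults here are desk-scale (small widths, few epochs and
    trees) so a full run finishes in well under a minute; the per-module
    library defaults carry the full-scale values.
    """

    seed: int = 1
    log_level: str = "INFO"
    fixture: dict = field(default_factory=dict)
    embed: EmbedBlock = field(default_factory=EmbedBlock)
    learner: LearnerBlock = field(default_factory=LearnerBlock)
    combiner: CombinerBlock = field(default_factory=CombinerBlock)
    phenomics: PhenomicsBlock = field(default_factory=PhenomicsBlock)
    networks: NetworksBlock = field(default_factory=NetworksBlock)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        blocks = {
            "embed": EmbedBlock,
            "learner": LearnerBlock,
            "combiner": CombinerBlock,
            "phenomics": PhenomicsBlock,
            "networks": NetworksBlock,
        }
        kwargs: dict = {}
        for key, blk in blocks.items():
            if key in data:
                kwargs[key] = _strict_make(blk, data.pop(key), key)
        if "fixture" in data:
            known = {f.name for f in fields(fixtures.FixtureSpec)}
            unknown = set(data["fixture"]) - known
            if unknown:
                raise ValueError(f"unknown config keys in fixture: {sorted(unknown)}")
            kwargs["fixture"] = data.pop("fixture")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def fixture_spec(self) -> fixtures.FixtureSpec:
        fx = dict(self.fixture)
        fx.setdefault("seed", self.seed)
        return fixtures.FixtureSpec(**fx)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_manifest(outdir: Path, stage: str, inputs: dict, outputs: list[Path], params: dict) -> None:
    mdir = outdir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    def rel(p: Path) -> str:
        try:
            return str(Path(p).relative_to(outdir))
        except ValueError:
            return str(p)

    manifest = {
        "stage": stage,
        "inputs": {rel(p): io.file_sha256(p) for p in inputs.values()},
        "outputs": {rel(p): io.file_sha256(p) for p in outputs},
        "params": params,
    }
    with open(mdir / f"{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _stage_fresh(outdir: Path, stage: str, inputs: dict) -> bool:
    mpath = outdir / "manifests" / f"{stage}.json"
    if not mpath.exists():
        return False
    manifest = json.loads(mpath.read_text())
    for section in ("inputs", "outputs"):
        for p, h in manifest[section].items():
            full = outdir / p if not Path(p).is_absolute() else Path(p)
            if not full.exists() or io.file_sha256(full) != h:
                return False
    return True


def run_pipeline(config: RunConfig, outdir, stages=STAGES, cache: bool = False) -> Path:
    """Execute the requested stages; returns the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": io.config_hash(config.as_dict())}
    paths = {
        "obo": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "cath_hits": outdir / "cath_hits.tsv",
        "pfam_hits": outdir / "pfam_hits.tsv",
        "cath_membership": outdir / "cath_membership.tsv",
        "pfam_membership": outdir / "pfam_membership.tsv",
        "fitness": outdir / "fitness.tsv",
        "condition_map": outdir / "condition_map.tsv",
        "ic": outdir / "ic.tsv",
        "embeddings": outdir / "embeddings.tsv",
        "nethom": outdir / "nethom_predictions.tsv",
        "cv_report": outdir / "nethom_cv_report.tsv",
        "cathpredict": outdir / "cathpredict_predictions.tsv",
        "combined": outdir / "netff_combined.tsv",
        "filtered": outdir / "netff_high_confidence.tsv",
        "gogo": outdir / "gogo_pairs.tsv",
        "hits_benign": outdir / "hits_benign.tsv",
        "hits_stress": outdir / "hits_stress.tsv",
        "ternary": outdir / "ternary.tsv",
        "clusters": outdir / "pam_clusters.tsv",
        "phephe": outdir / "phephe_pairs.tsv",
        "network": outdir / "phenotype_network.graphml",
        "communities": outdir / "communities.tsv",
        "integration": outdir / "integration_edges.tsv",
        "integration_control": outdir / "integration_control.tsv",
    }
    layer_paths = {name: outdir / f"network_{name}.tsv" for name in embedding.LAYER_NAMES}
    spec = config.fixture_spec()

    def want(stage: str) -> bool:
        return stage in stages

    missing = [s for s in stages if s not in STAGES]
    if missing:
        raise PipelineError(f"unknown stages: {missing}")

    # ---------------------------------------------------------------- simulate
    if want("simulate"):
        inputs: dict = {}
        if not (cache and _stage_fresh(outdir, "simulate", inputs)):
            graph, annotations, truth = fixtures.make_ontology(spec)
            io.write_obo(graph, paths["obo"])
            io.write_annotations_tsv(annotations, paths["annotations"], meta)
            edge_lists, _ = fixtures.make_networks(spec)
            for name, df in edge_lists.items():
                io.write_edge_list(df, layer_paths[name], meta)
            cath_m, cath_h, pfam_m, pfam_h, _ = fixtures.make_families(spec, annotations, truth)
            io.write_hits_tsv(cath_h, paths["cath_hits"])
            io.write_hits_tsv(pfam_h, paths["pfam_hits"])
            io.write_membership_tsv(cath_m, paths["cath_membership"])
            io.write_membership_tsv(pfam_m, paths["pfam_membership"])
            fitness, cmap, ph_truth = fixtures.make_phenotypes(spec)
            io.write_table(fitness, paths["fitness"], meta)
            io.write_table(cmap, paths["condition_map"], meta)
            tdir = outdir / "truth"
            tdir.mkdir(exist_ok=True)
            io.write_table(ph_truth["hits"], tdir / "hits.tsv", meta)
            io.write_table(ph_truth["clusters"], tdir / "clusters.tsv", meta)
            modules_df = pd.DataFrame(sorted(truth["modules"].items()), columns=["gene", "module"])
            io.write_table(modules_df, tdir / "modules.tsv", meta)
            _write_manifest(
                outdir, "simulate", inputs,
                [paths[k] for k in ("obo", "annotations", "cath_hits", "pfam_hits",
                                    "cath_membership", "pfam_membership", "fitness", "condition_map")]
                + list(layer_paths.values()),
                {"seed": config.seed},
            )

    def require(*keys: str) -> dict:
        got = {}
        for k in keys:
            p = paths.get(k, layer_paths.get(k))
            if p is None or not Path(p).exists():
                raise PipelineError(f"missing upstream artifact for stage: {k} ({p})")
            got[k] = p
        return got

    graph = ontology.load_obo(str(paths["obo"])) if Path(paths["obo"]).exists() else None
    annotations = io.read_annotations_tsv(paths["annotations"]) if Path(paths["annotations"]).exists() else None

    # ---------------------------------------------------------------- ontology
    if want("ontology"):
        inputs = require("obo", "annotations")
        if not (cache and _stage_fresh(outdir, "ontology", inputs)):
            ic = ontology.information_content(annotations, graph)
            io.write_table(ic.to_frame(), paths["ic"], meta)
            _write_manifest(outdir, "ontology", inputs, [paths["ic"]], {})

    # ---------------------------------------------------------------- embed
    if want("embed"):
        inputs = require(*embedding.LAYER_NAMES)
        if not (cache and _stage_fresh(outdir, "embed", inputs)):
            edge_lists = {n: io.read_edge_list(layer_paths[n]) for n in embedding.LAYER_NAMES}
            stack = embedding.build_stack(edge_lists, spec.genes())
            cfg = embedding.AutoencoderConfig(
                hidden=config.embed.hidden,
                embedding_dim=config.embed.embedding_dim,
                epochs=config.embed.epochs,
                batch_size=config.embed.batch_size,
                learning_rate=config.embed.learning_rate,
                activation=config.embed.activation,
                preprocess_rwr_ppmi=config.embed.preprocess_rwr_ppmi,
                seed=config.seed,
            )
            emb = embedding.train_autoencoder(stack, cfg)
            embedding.export_embeddings(emb, paths["embeddings"])
            _write_manifest(outdir, "embed", inputs, [paths["embeddings"]],
                            {"selected_epoch": emb.meta["selected_epoch"]})

    # ---------------------------------------------------------------- nethom
    if want("nethom"):
        inputs = require("embeddings", "obo", "annotations", "cath_hits", "cath_membership")
        if not (cache and _stage_fresh(outdir, "nethom", inputs)):
            emb = embedding.read_embeddings(paths["embeddings"])
            hits = funfam.filter_hits(funfam.parse_domtbl(paths["cath_hits"]))
            fam_matrix = funfam.build_feature_matrix(hits, proteins=emb.genes)
            X = np.hstack([emb.values, fam_matrix.to_dense()])
            lb = config.learner
            targets = learner.select_targets(
                annotations, graph, mode=lb.target_mode, lo=lb.target_lo, hi=lb.target_hi,
                genes=emb.genes, namespace=lb.namespace,
            )
            membership = io.read_membership_tsv(paths["cath_membership"])
            masks = learner.family_column_mask(
                emb.values.shape[1], fam_matrix.families, membership, annotations, graph, targets.terms
            )
            cfg = learner.ForestConfig(
                n_trees=lb.n_trees, max_features=lb.max_features,
                partial_sampling=lb.partial_sampling, seed=config.seed,
            )
            scores, report = learner.cross_validate(
                X, targets, cfg, folds=lb.folds, trials=lb.trials, term_masks=masks
            )
            S = scores[0]
            rows = [
                (g, t, float(S[i, j]), "nethom", graph.namespace(t))
                for i, g in enumerate(targets.genes)
                for j, t in enumerate(targets.terms)
                if S[i, j] > 0
            ]
            preds = pd.DataFrame(rows, columns=["gene", "term", "score", "source", "namespace"])
            io.write_table(preds, paths["nethom"], meta)
            io.write_table(report, paths["cv_report"], meta)
            _write_manifest(outdir, "nethom", inputs, [paths["nethom"], paths["cv_report"]],
                            {"targets": len(targets.terms)})

    # ---------------------------------------------------------------- cathpredict
    if want("cathpredict"):
        inputs = require("cath_hits", "pfam_hits", "cath_membership", "pfam_membership", "obo", "annotations")
        if not (cache and _stage_fresh(outdir, "cathpredict", inputs)):
            cath_h = funfam.parse_domtbl(paths["cath_hits"], source="cath")
            pfam_h = funfam.parse_domtbl(paths["pfam_hits"], source="pfam")
            cath_go = funfam.associate_family_go(io.read_membership_tsv(paths["cath_membership"]), annotations, graph)
            pfam_go = funfam.associate_family_go(io.read_membership_tsv(paths["pfam_membership"]), annotations, graph)
            preds = funfam.cathpredict(cath_h, pfam_h, cath_go, pfam_go)
            preds["namespace"] = [graph.namespace(t) if t in graph else "" for t in preds["term"]]
            io.write_table(preds, paths["cathpredict"], meta)
            _write_manifest(outdir, "cathpredict", inputs, [paths["cathpredict"]], {})

    # ---------------------------------------------------------------- combine
    if want("combine"):
        inputs = require("nethom", "cathpredict", "ic", "obo", "annotations")
        if not (cache and _stage_fresh(outdir, "combine", inputs)):
            nethom_df, _ = io.read_table(paths["nethom"])
            cath_df, _ = io.read_table(paths["cathpredict"])
            combined = combiner.combine(nethom_df, cath_df)
            ic_df, _ = io.read_table(paths["ic"])
            ic_table = ontology.ICTable(
                p=dict(zip(ic_df["term"], ic_df["p"])),
                ic=dict(zip(ic_df["term"], ic_df["ic"])),
            )
            combined = ontology.ic_for_new_terms(combined, ic_table)
            filtered, counts = combiner.filter_high_confidence(
                combined, score_min=config.combiner.score_min, ic_min=config.combiner.ic_min,
                banned_terms=config.combiner.banned_terms, graph=graph,
            )
            filtered = combiner.partition_novelty(filtered, annotations, graph)
            io.write_table(combined, paths["combined"], meta)
            io.write_table(filtered, paths["filtered"], meta)
            _write_manifest(outdir, "combine", inputs, [paths["combined"], paths["filtered"]], counts)

    # ---------------------------------------------------------------- gogo
    if want("gogo"):
        inputs = require("obo", "annotations")
        if not (cache and _stage_fresh(outdir, "gogo", inputs)):
            table = similarity.all_vs_all_gogo(annotations, None, graph, namespaces=("BP",))
            io.write_table(table, paths["gogo"], meta)
            _write_manifest(outdir, "gogo", inputs, [paths["gogo"]], {})

    # ---------------------------------------------------------------- pheno
    if want("pheno"):
        inputs = require("fitness", "condition_map")
        if not (cache and _stage_fresh(outdir, "pheno", inputs)):
            fitness, _ = io.read_table(paths["fitness"])
            cmap, _ = io.read_table(paths["condition_map"])
            pb = config.phenomics
            benign_conds = list(cmap.loc[cmap["is_benign"].astype(bool), "condition"])
            hits_b = phenomics.call_benign(
                fitness.loc[fitness["condition"].isin(benign_conds)],
                alpha=pb.alpha, effect=pb.benign_effect,
            )
            hits_s = phenomics.call_stress(fitness, cmap, effect=pb.stress_effect)
            ternary = phenomics.discretize(
                hits_s[["strain", "condition", "score"]], hits_b,
                effect=pb.ternary_effect, alpha=pb.alpha,
            )
            filtered_m = phenomics.filter_matrix(ternary, mode=pb.filter_mode)
            clusters = phenomics.pam_cluster(
                filtered_m, k_range=range(pb.k_min, pb.k_max + 1),
                min_overlap=pb.min_overlap, seed=config.seed,
            )
            io.write_table(hits_b, paths["hits_benign"], meta)
            io.write_table(hits_s, paths["hits_stress"], meta)
            io.write_table(ternary.reset_index(), paths["ternary"], meta)
            io.write_table(clusters, paths["clusters"], meta)
            _write_manifest(outdir, "pheno", inputs,
                            [paths[k] for k in ("hits_benign", "hits_stress", "ternary", "clusters")],
                            {"k": int(clusters["k"].iloc[0])})

    # ---------------------------------------------------------------- networks
    if want("networks"):
        inputs = require("fitness", "condition_map", "gogo")
        if not (cache and _stage_fresh(outdir, "networks", inputs)):
            fitness, _ = io.read_table(paths["fitness"])
            cmap, _ = io.read_table(paths["condition_map"])
            nb = config.networks
            scores = phenomics.stress_scores(fitness, cmap)
            profiles = scores.pivot_table(index="strain", columns="condition", values="score")
            pp = networks.phephe(profiles, min_overlap=nb.min_overlap)
            graph_net = networks.build_network(pp, rmin=nb.rmin, pmax=nb.pmax)
            comms = networks.community_clusters(graph_net, seed=config.seed)
            gogo_df, _ = io.read_table(paths["gogo"])
            integ = networks.integrate_gogo_phephe(
                gogo_df.loc[gogo_df["namespace"] == "BP"], pp,
                gate=nb.gate, product_gate=nb.product_gate,
            )
            control = networks.random_control_network(
                gogo_df.loc[gogo_df["namespace"] == "BP"], pp, seed=config.seed,
                gate=nb.gate, product_gate=nb.product_gate,
            )
            io.write_table(pp, paths["phephe"], meta)
            networks.export_graphml(graph_net, paths["network"])
            io.write_table(
                pd.DataFrame(sorted(comms.items()), columns=["gene", "cluster"]),
                paths["communities"], meta,
            )
            io.write_table(integ, paths["integration"], meta)
            io.write_table(control, paths["integration_control"], meta)
            _write_manifest(outdir, "networks", inputs,
                            [paths[k] for k in ("phephe", "communities", "integration", "integration_control")],
                            {"edges": graph_net.number_of_edges(), "integration_edges": len(integ)})

    return outdir
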