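"""Round-trip-safe readers and writers for the interchange formats.

All tables are tab-separated UTF-8; writers prepend ``#``-prefixed metadata
lines (tool version, config hash, seed) that readers return alongside the
frame. Domain-hit coordinates are 1-based inclusive (HMMER convention).
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .ontology import GeneAnnotationSet, OntologyGraph

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- TSV tables

def write_table(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    meta = dict(meta or {})
    meta.setdefault("tool_version", __version__)
    with open(path, "w") as fh:
        for k in sorted(meta):
            fh.write(f"# {k}={meta[k]}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path, index_col=None) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=index_col)
    return df, meta


def config_hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------- annotations

def read_gaf(path) -> GeneAnnotationSet:
    """GAF 2.x reader using columns 2 (gene), 5 (term), 7 (evidence), 9 (aspect)."""
    out = GeneAnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 15:
                raise FormatError(f"{path}:{lineno}: GAF row has {len(fields)} columns, expected >=15")
            gene, term, evidence = fields[1], fields[4], fields[6]
            out.add(gene, term, evidence)
    return out


def read_annotations_tsv(path) -> GeneAnnotationSet:
    """Minimal 3-column TSV: gene, term, evidence (header optional)."""
    out = GeneAnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            if fields[0].lower() in ("gene", "gene_id"):  # header row
                continue
            gene, term = fields[0], fields[1]
            evidence = fields[2] if len(fields) > 2 else "IEA"
            out.add(gene, term, evidence)
    return out


def write_annotations_tsv(annotations: GeneAnnotationSet, path, meta: dict | None = None) -> None:
    rows = list(annotations.records())
    df = pd.DataFrame(rows, columns=["gene", "term", "evidence"])
    write_table(df, path, meta)


# ---------------------------------------------------------------- ontology

def write_obo(graph: OntologyGraph, path) -> None:
    """Minimal OBO 1.2 writer (round-trips through the obonet-backed reader)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: synthetic\n")
        ns_names = {"BP": "biological_process", "MF": "molecular_function", "CC": "cellular_component"}
        for term in sorted(graph.terms):
            info = graph.terms[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {info.name}\n")
            fh.write(f"namespace: {ns_names.get(info.namespace, info.namespace)}\n")
            for alt, primary in sorted(graph.alt_ids.items()):
                if primary == term:
                    fh.write(f"alt_id: {alt}\n")
            if info.obsolete:
                fh.write("is_obsolete: true\n")
                continue
            for parent, rel in sorted(graph._parents[term]):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


# ---------------------------------------------------------------- misc tables

def write_edge_list(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(df[["geneA", "geneB", "weight"]], path, meta)


def read_edge_list(path) -> pd.DataFrame:
    df, _ = read_table(path)
    missing = {"geneA", "geneB", "weight"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: edge list missing columns {sorted(missing)}")
    if (df["weight"] < 0).any():
        raise FormatError(f"{path}: negative edge weight")
    return df


def write_hits_tsv(hits, path) -> None:
    rows = [(h.protein, h.family, h.evalue, h.bitscore, h.start, h.stop) for h in hits]
    df = pd.DataFrame(rows, columns=["protein", "family", "evalue", "bitscore", "start", "stop"])
    with open(path, "w") as fh:
        fh.write("# columns: protein family evalue bitscore env_start env_stop (1-based inclusive)\n")
        df.to_csv(fh, sep="\t", index=False, header=False, float_format="%.6g")


def write_membership_tsv(membership: dict, path) -> None:
    rows = [(f, p) for f, members in sorted(membership.items()) for p in members]
    write_table(pd.DataFrame(rows, columns=["family", "protein"]), path)


def read_membership_tsv(path) -> dict[str, list[str]]:
    df, _ = read_table(path)
    out: dict[str, list[str]] = {}
    for fam, prot in df[["family", "protein"]].itertuples(index=False):
        out.setdefault(fam, []).append(prot)
    return out


# ---------------------------------------------------------------- validation

def validate_files(paths: dict[str, str | Path]) -> list[str]:
    """Dialect checks per declared kind; returns a list of error strings.

    ``paths`` maps kind -> path with kinds: obo, gaf, annotations, domtbl,
    edge_list, fitness, condition_map.
    """
    errors: list[str] = []
    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            errors.append(f"{path}: missing file")
            continue
        try:
            if kind == "obo":
                from .ontology import load_obo

                load_obo(str(path))
            elif kind == "gaf":
                read_gaf(path)
            elif kind == "annotations":
                read_annotations_tsv(path)
            elif kind == "domtbl":
                from .funfam import parse_domtbl

                parse_domtbl(path)
            elif kind == "edge_list":
                read_edge_list(path)
            elif kind == "fitness":
                df, _ = read_table(path)
                need = {"strain", "condition", "repeat", "fitness"}
                if not need <= set(df.columns):
                    raise FormatError(f"fitness table missing {sorted(need - set(df.columns))}")
                if (df["fitness"] <= 0).any():
                    raise FormatError("non-positive fitness value")
            elif kind == "condition_map":
                df, _ = read_table(path)
                need = {"condition", "control", "is_benign"}
                if not need <= set(df.columns):
                    raise FormatError(f"condition map missing {sorted(need - set(df.columns))}")
            else:
                raise FormatError(f"unknown file kind: {kind}")
        except Exception as exc:
            errors.append(f"{path}: {exc}")
    return errors
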