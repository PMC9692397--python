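"""Readers and writers for the pipeline's plain-text formats.

Counts and tables travel as TSV; pathway membership as GMT (name,
description, members) and intra-pathway interactions as 3-column SIF
(source, relation, target).  Writers can stamp outputs with a comment
line carrying the configuration hash and seed; readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .de import CountMatrix
from .network import PathwayCollection

__all__ = [
    "config_hash",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_de_table",
    "write_table",
    "read_table",
    "read_gmt",
    "write_gmt",
    "read_sif",
    "write_sif",
    "read_pathways",
    "write_pathways",
]


def config_hash(params: Mapping) -> str:
    """Short stable hash of a parameter mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stamp_line(stamp: Mapping | None) -> str | None:
    if stamp is None:
        return None
    fields = " ".join(f"{k}={v}" for k, v in stamp.items())
    return f"# hormonet {fields}\n"


def write_table(
    df: pd.DataFrame, path: str | Path, stamp: Mapping | None = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        line = _stamp_line(stamp)
        if line:
            fh.write(line)
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_counts_tsv(
    counts: CountMatrix, path: str | Path, stamp: Mapping | None = None
) -> None:
    df = counts.counts.copy()
    df.index.name = "gene_id"
    write_table(df, path, stamp=stamp, index=True)


def read_counts_tsv(path: str | Path) -> CountMatrix:
    """Counts TSV with a ``gene_id`` column and ``COND_rep`` sample columns."""
    df = read_table(path).set_index("gene_id")
    return CountMatrix.from_dataframe(df)


def read_de_table(path: str | Path) -> pd.DataFrame:
    """A precomputed DE table (gene_id, contrast, log2fc, p, fdr, is_de)."""
    df = read_table(path)
    required = {"gene_id", "contrast", "is_de"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if df["is_de"].dtype == object:
        df["is_de"] = df["is_de"].map(
            {"True": True, "False": False, "true": True, "false": False}
        ).astype(bool)
    return df


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in collection.names:
            members = "\t".join(sorted(collection.members(name)))
            fh.write(f"{name}\t{name}\t{members}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    members = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            members[parts[0]] = parts[2:]
    return members


def write_sif(collection: PathwayCollection, path: str | Path) -> None:
    """All pathway edges as ``source<TAB>interacts<TAB>target`` (deduplicated)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seen = set()
    with open(path, "w") as fh:
        for name in collection.names:
            for edge in sorted(tuple(sorted(e)) for e in collection.edges(name)):
                if edge in seen:
                    continue
                seen.add(edge)
                fh.write(f"{edge[0]}\tinteracts\t{edge[1]}\n")


def read_sif(path: str | Path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            edges.append((parts[0], parts[2]))
    return edges


def write_pathways(
    collection: PathwayCollection, gmt_path: str | Path, sif_path: str | Path
) -> None:
    write_gmt(collection, gmt_path)
    write_sif(collection, sif_path)


def read_pathways(gmt_path: str | Path, sif_path: str | Path) -> PathwayCollection:
    """Assemble a collection from GMT membership and a global SIF edge list.

    Each SIF edge is attached to every pathway containing both endpoints;
    edges whose endpoints share no pathway are rejected.
    """
    members = read_gmt(gmt_path)
    edge_list = read_sif(sif_path)
    norm_members = {
        name: {g.upper() for g in genes} for name, genes in members.items()
    }
    edges: dict[str, list[tuple[str, str]]] = {name: [] for name in members}
    for a, b in edge_list:
        a_u, b_u = a.upper(), b.upper()
        if a_u == b_u:
            continue
        hit = False
        for name, genes in norm_members.items():
            if a_u in genes and b_u in genes:
                edges[name].append((a, b))
                hit = True
        if not hit:
            raise ValueError(
                f"edge ({a}, {b}) does not fall inside any pathway"
            )
    return PathwayCollection.from_dict(members, edges)
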