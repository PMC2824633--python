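"""Readers and writers for the plain-text formats used across the pipeline.

All tables are TSV.  Gene sets use GMT (one category per line: id, description,
members).  Edge lists are 2-column TSV or 3-column SIF (node relation node).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import networkx as nx
import pandas as pd

EXPRESSION_COLUMNS = ["probe_id", "condition", "ratio"]
PROBE_MAP_COLUMNS = ["probe_id", "gene_id"]
CT_COLUMNS = ["sample", "gene", "replicate", "ct"]


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return df[EXPRESSION_COLUMNS]


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROBE_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe map missing columns: {sorted(missing)}")
    return df[PROBE_MAP_COLUMNS]


def write_probe_map(df: pd.DataFrame, path: str | Path) -> None:
    df[PROBE_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected simple graph from 2-column TSV or 3-column SIF.

    Self-loops are dropped; duplicate edges collapse silently.
    """
    graph = nx.Graph()
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fields[0] in ("node_a", "source"):  # header
                continue
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:  # SIF: node relation node
                a, _, b = fields
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}")
            if a != b:
                graph.add_edge(a, b)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("node_a\tnode_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            handle.write(f"{a}\t{b}\n")


def read_gmt(path: str | Path) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Return (category id -> members, category id -> description)."""
    categories: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, description, >=1 member")
            cid, desc, members = fields[0], fields[1], fields[2:]
            if cid in categories:
                raise ValueError(f"{path}:{lineno}: duplicate category id {cid!r}")
            categories[cid] = [m for m in members if m]
            names[cid] = desc
    return categories, names


def write_gmt(categories: dict[str, list[str] | frozenset[str]],
              names: dict[str, str] | None,
              path: str | Path) -> None:
    names = names or {}
    with open(path, "w") as handle:
        for cid, members in categories.items():
            desc = names.get(cid, cid)
            handle.write("\t".join([cid, desc, *sorted(members)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip() and not line.startswith("#")]


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as handle:
        for gene in genes:
            handle.write(f"{gene}\n")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    return df[CT_COLUMNS]


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df[CT_COLUMNS].to_csv(path, sep="\t", index=False)


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
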