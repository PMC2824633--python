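"""Deregulated-gene calling: fold-change filter, probe-to-gene collapse, and
the unique/common partition between two conditions.

A probe passes the filter at threshold ``t`` iff its linear ratio is ``>= t``
(up) or ``<= 1/t`` (down); "at least t-fold" is read inclusively.  A gene is
deregulated iff at least one of its probes passes; its representative fold
change is the most extreme passing ratio in the called direction.  Genes with
passing probes in both directions are flagged discordant and excluded from
both sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "filter_probes",
    "collapse_to_genes",
    "partition_sets",
    "call_deregulated",
    "GeneCollapse",
    "DeregulatedSets",
    "Partition",
    "write_partition_table",
]


def filter_probes(table: pd.DataFrame, condition: str, threshold: float = 2.0) -> pd.DataFrame:
    """Select probes altered at least ``threshold``-fold in ``condition``.

    Returns a frame with columns ``probe_id, ratio, direction``
    (direction in {"up", "down"}).  Boundary values pass.
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    if condition not in set(table["condition"]):
        raise ValueError(f"unknown condition {condition!r}")
    sub = table[table["condition"] == condition]
    if (sub["ratio"] <= 0).any():
        raise ValueError("ratios must be strictly positive")
    up = sub["ratio"] >= threshold
    down = sub["ratio"] <= 1.0 / threshold
    out = sub.loc[up | down, ["probe_id", "ratio"]].copy()
    out["direction"] = np.where(out["ratio"] >= threshold, "up", "down")
    return out.reset_index(drop=True)


@dataclass
class GeneCollapse:
    """Gene-level calls after collapsing probes.

    ``calls`` has columns ``gene_id, direction, fold_change`` (one row per
    gene).  ``discordant`` lists genes excluded for passing in both
    directions; ``unmapped`` lists selected probes missing from the map.
    """

    calls: pd.DataFrame
    discordant: list[str] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)

    def genes(self, direction: str | None = None) -> set[str]:
        if direction is None:
            return set(self.calls["gene_id"])
        return set(self.calls.loc[self.calls["direction"] == direction, "gene_id"])

    def fold_change(self, gene: str) -> float:
        row = self.calls[self.calls["gene_id"] == gene]
        if row.empty:
            raise KeyError(gene)
        return float(row["fold_change"].iloc[0])


def collapse_to_genes(selected: pd.DataFrame, probe_map: pd.DataFrame) -> GeneCollapse:
    """Collapse a filtered probe set (from :func:`filter_probes`) to genes.

    Representative fold change: min passing ratio for a down gene, max for an
    up gene.  Unmapped probes are reported, not silently dropped.
    """
    mapping = dict(zip(probe_map["probe_id"], probe_map["gene_id"]))
    unmapped = sorted(p for p in selected["probe_id"] if p not in mapping)
    merged = selected[selected["probe_id"].isin(mapping)].copy()
    merged["gene_id"] = merged["probe_id"].map(mapping)

    rows = []
    discordant: list[str] = []
    for gene, grp in merged.groupby("gene_id", sort=True):
        dirs = set(grp["direction"])
        if dirs == {"up", "down"}:
            discordant.append(gene)
            continue
        if "down" in dirs:
            rows.append((gene, "down", float(grp["ratio"].min())))
        else:
            rows.append((gene, "up", float(grp["ratio"].max())))
    calls = pd.DataFrame(rows, columns=["gene_id", "direction", "fold_change"])
    return GeneCollapse(calls=calls, discordant=sorted(discordant), unmapped=unmapped)


@dataclass
class Partition:
    """Unique/common split of two conditions' deregulated gene sets."""

    condition_a: str
    condition_b: str
    unique_a: pd.DataFrame    # gene_id, direction, fold_change
    unique_b: pd.DataFrame
    common: pd.DataFrame      # gene_id, fold_change_a, fold_change_b, direction_a, direction_b


def partition_sets(calls_a: GeneCollapse, calls_b: GeneCollapse,
                   condition_a: str = "A", condition_b: str = "B") -> Partition:
    """Exact set difference / intersection of two gene-level call sets.

    Common membership requires passing in both conditions regardless of
    direction agreement; disagreement is visible via the two direction
    columns.
    """
    genes_a, genes_b = calls_a.genes(), calls_b.genes()
    common_genes = sorted(genes_a & genes_b)

    unique_a = calls_a.calls[~calls_a.calls["gene_id"].isin(common_genes)].reset_index(drop=True)
    unique_b = calls_b.calls[~calls_b.calls["gene_id"].isin(common_genes)].reset_index(drop=True)

    a_idx = calls_a.calls.set_index("gene_id")
    b_idx = calls_b.calls.set_index("gene_id")
    common = pd.DataFrame({
        "gene_id": common_genes,
        "fold_change_a": [float(a_idx.loc[g, "fold_change"]) for g in common_genes],
        "fold_change_b": [float(b_idx.loc[g, "fold_change"]) for g in common_genes],
        "direction_a": [a_idx.loc[g, "direction"] for g in common_genes],
        "direction_b": [b_idx.loc[g, "direction"] for g in common_genes],
    })
    return Partition(condition_a, condition_b, unique_a, unique_b, common)


@dataclass
class DeregulatedSets:
    """Per-condition gene calls plus the pairwise partition of the first two."""

    conditions: list[str]
    collapses: dict[str, GeneCollapse]
    partition: Partition | None

    def genes(self, condition: str, direction: str | None = None) -> set[str]:
        return self.collapses[condition].genes(direction)


def call_deregulated(table: pd.DataFrame, probe_map: pd.DataFrame,
                     threshold: float = 2.0,
                     conditions: list[str] | None = None) -> DeregulatedSets:
    """Filter, collapse, and (for the first two conditions) partition."""
    if conditions is None:
        conditions = sorted(set(table["condition"]))
    collapses = {
        cond: collapse_to_genes(filter_probes(table, cond, threshold), probe_map)
        for cond in conditions
    }
    partition = None
    if len(conditions) >= 2:
        a, b = conditions[0], conditions[1]
        partition = partition_sets(collapses[a], collapses[b], a, b)
    return DeregulatedSets(list(conditions), collapses, partition)


def write_partition_table(partition: Partition, path: str | Path) -> None:
    """Three-block TSV (unique-A, unique-B, common), each block sorted
    ascending by fold change."""
    with open(path, "w") as handle:
        handle.write("block\tgene_id\tfold_change_a\tfold_change_b\tdirection\n")
        a, b = partition.condition_a, partition.condition_b
        ua = partition.unique_a.sort_values("fold_change")
        for _, row in ua.iterrows():
            handle.write(f"unique_{a}\t{row.gene_id}\t{row.fold_change:.6g}\t\t{row.direction}\n")
        ub = partition.unique_b.sort_values("fold_change")
        for _, row in ub.iterrows():
            handle.write(f"unique_{b}\t{row.gene_id}\t\t{row.fold_change:.6g}\t{row.direction}\n")
        co = partition.common.sort_values("fold_change_a")
        for _, row in co.iterrows():
            direction = row.direction_a if row.direction_a == row.direction_b else "discordant"
            handle.write(
                f"common\t{row.gene_id}\t{row.fold_change_a:.6g}"
                f"\t{row.fold_change_b:.6g}\t{direction}\n")
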