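"""Synthetic expression tables, probe maps, interactomes, annotation catalogs
and qPCR plates with planted ground truth.

The generator emulates a two-knockdown-plus-control array design: linear-scale
expression ratios per probe and condition, a many-to-one probe-to-gene map, an
undirected interactome that misses a configurable fraction of the gene
universe, a 38-pathway annotation collection one member of which coincides
with a densely wired graph module whose genes are planted as downregulated,
and CT plates that invert exactly through the comparative-CT pipeline at zero
noise.

Determinism: every artifact draws from its own child stream of a single root
seed, so regenerating one artifact never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SyntheticDesign",
    "SyntheticTruth",
    "generate_expression",
    "generate_ppi",
    "generate_catalog",
    "generate_qpcr_plate",
]

_STREAMS = {"plant": 0, "probes": 1, "expr": 2, "ppi": 3,
            "catalog_kegg": 4, "catalog_go": 5, "qpcr": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one synthetic experiment.

    ``planted_down`` / ``planted_up`` map condition label to ``(size, ratio)``:
    how many genes are planted in that direction and at which linear-scale
    effect.  Down ratios must be < 0.5 and up ratios > 2.0 so the planting is
    detectable by the 2-fold filter in expectation.  ``n_common_down`` genes
    are planted down in both of the first two conditions, giving the
    unique/common partition a non-trivial ground truth.
    """

    n_genes: int = 12000
    n_probes: int = 13800
    conditions: tuple[str, ...] = ("kd1", "kd2")
    planted_down: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {"kd1": (60, 0.25), "kd2": (40, 0.3)})
    planted_up: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {"kd1": (20, 4.0), "kd2": (15, 4.0)})
    n_common_down: int = 12
    noise_sd: float = 0.1
    ppi_m: int = 2                    # preferential-attachment edges per node
    ppi_absent_fraction: float = 0.2  # genes deliberately missing from the graph
    planted_module: str = "PW01"
    planted_module_size: int = 20
    module_edge_prob: float = 0.9
    n_pathways: int = 38
    n_go_terms: int = 50
    category_size_range: tuple[int, int] = (10, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_probes < self.n_genes:
            raise ValueError("n_probes must be >= n_genes (many-to-one map)")
        if len(self.conditions) < 1:
            raise ValueError("at least one condition required")
        for cond, (size, ratio) in self.planted_down.items():
            if cond not in self.conditions:
                raise ValueError(f"planted_down condition {cond!r} not in conditions")
            if size < 0 or ratio <= 0 or ratio >= 0.5:
                raise ValueError(f"down effect for {cond!r} must satisfy 0 < ratio < 0.5")
        for cond, (size, ratio) in self.planted_up.items():
            if cond not in self.conditions:
                raise ValueError(f"planted_up condition {cond!r} not in conditions")
            if size < 0 or ratio <= 2.0:
                raise ValueError(f"up effect for {cond!r} must satisfy ratio > 2.0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ppi_m < 0:
            raise ValueError("ppi_m must be >= 0")
        if not 0 <= self.ppi_absent_fraction < 1:
            raise ValueError("ppi_absent_fraction must be in [0, 1)")
        if not 0 <= self.module_edge_prob <= 1:
            raise ValueError("module_edge_prob must be in [0, 1]")
        lo, hi = self.category_size_range
        if lo < 1 or hi < lo or hi > self.n_genes:
            raise ValueError("category_size_range must satisfy 1 <= lo <= hi <= n_genes")
        first = self.conditions[0]
        d0 = self.planted_down.get(first, (0, 0.25))[0]
        if self.planted_module_size > d0:
            raise ValueError(
                "planted_module_size exceeds the planted-down size of the first condition")
        if len(self.conditions) > 1:
            d1 = self.planted_down.get(self.conditions[1], (0, 0.25))[0]
            if self.n_common_down > min(d0, d1):
                raise ValueError("n_common_down exceeds a planted-down set size")
        total = sum(s for s, _ in self.planted_down.values()) \
            + sum(s for s, _ in self.planted_up.values()) - self.n_common_down
        if total > self.n_genes:
            raise ValueError("planted sets exceed the gene universe")

    @property
    def universe(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted labels: which gene carries which effect in which condition."""

    universe: tuple[str, ...]
    module_genes: tuple[str, ...]
    effects: Mapping[tuple[str, str], float]  # (gene, condition) -> linear ratio
    table: pd.DataFrame                       # gene, condition, direction, ratio

    def planted(self, condition: str, direction: str | None = None) -> set[str]:
        sub = self.table[self.table["condition"] == condition]
        if direction is not None:
            sub = sub[sub["direction"] == direction]
        return set(sub["gene"])

    def ratio(self, gene: str, condition: str) -> float:
        return self.effects.get((gene, condition), 1.0)


def plant(design: SyntheticDesign) -> SyntheticTruth:
    """Assign planted effects to genes; deterministic in ``design.seed``.

    The dense graph module coincides with the first ``planted_module_size``
    down genes of the first condition.  The first ``n_common_down`` module
    genes are also planted down in the second condition, forming the common
    set.
    """
    rng = _rng(design.seed, "plant")
    universe = design.universe
    perm = [universe[i] for i in rng.permutation(design.n_genes)]
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = perm[cursor:cursor + k]
        cursor += k
        return out

    conds = design.conditions
    down: dict[str, list[str]] = {}
    up: dict[str, list[str]] = {}

    d0_size = design.planted_down.get(conds[0], (0, 0.25))[0]
    down[conds[0]] = take(d0_size)
    module_genes = tuple(down[conds[0]][:design.planted_module_size])
    common = down[conds[0]][:design.n_common_down] if len(conds) > 1 else []

    for cond in conds[1:]:
        size = design.planted_down.get(cond, (0, 0.25))[0]
        if cond == conds[1]:
            down[cond] = list(common) + take(size - len(common))
        else:
            down[cond] = take(size)
    for cond in conds:
        size = design.planted_up.get(cond, (0, 4.0))[0]
        up[cond] = take(size)

    effects: dict[tuple[str, str], float] = {}
    rows = []
    for cond in conds:
        ratio_down = design.planted_down.get(cond, (0, 0.25))[1]
        ratio_up = design.planted_up.get(cond, (0, 4.0))[1]
        for gene in down.get(cond, []):
            effects[(gene, cond)] = ratio_down
            rows.append((gene, cond, "down", ratio_down))
        for gene in up.get(cond, []):
            effects[(gene, cond)] = ratio_up
            rows.append((gene, cond, "up", ratio_up))
    table = pd.DataFrame(rows, columns=["gene", "condition", "direction", "ratio"])
    return SyntheticTruth(tuple(universe), module_genes, effects, table)


def generate_probe_map(design: SyntheticDesign) -> pd.DataFrame:
    """Many-to-one probe-to-gene map: one probe per gene, surplus probes
    assigned to uniformly drawn genes."""
    rng = _rng(design.seed, "probes")
    genes = design.universe
    targets = list(genes)
    extra = design.n_probes - design.n_genes
    targets += [genes[i] for i in rng.integers(0, design.n_genes, size=extra)]
    probes = [f"P{i:06d}" for i in range(design.n_probes)]
    return pd.DataFrame({"probe_id": probes, "gene_id": targets})


def generate_expression(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Per-probe linear expression ratios for every condition.

    Each probe's ratio is the planted effect of its gene (1.0 if unplanted)
    times ``2**eps`` with ``eps ~ Normal(0, noise_sd)``.

    Returns ``(expression table, probe map, truth)``.
    """
    truth = plant(design)
    probe_map = generate_probe_map(design)
    rng = _rng(design.seed, "expr")
    rows = []
    for cond in design.conditions:
        eps = rng.normal(0.0, design.noise_sd, size=design.n_probes)
        for i, (probe, gene) in enumerate(zip(probe_map["probe_id"], probe_map["gene_id"])):
            base = truth.ratio(gene, cond)
            rows.append((probe, cond, base * 2.0 ** eps[i]))
    table = pd.DataFrame(rows, columns=["probe_id", "condition", "ratio"])
    return table, probe_map, truth


def generate_ppi(design: SyntheticDesign) -> nx.Graph:
    """Undirected simple interactome over a subset of the gene universe.

    Backbone is preferential attachment with ``ppi_m`` edges per node
    (``ppi_m = 0`` gives an edgeless graph).  A fraction of genes is absent
    from the graph altogether; planted-module genes are always present and are
    additionally wired pairwise with probability ``module_edge_prob``.
    """
    truth = plant(design)
    rng = _rng(design.seed, "ppi")
    module = set(truth.module_genes)
    others = [g for g in design.universe if g not in module]
    n_keep = int(round(len(others) * (1.0 - design.ppi_absent_fraction)))
    keep_idx = rng.choice(len(others), size=n_keep, replace=False)
    nodes = sorted(module) + sorted(others[i] for i in keep_idx)
    order = [nodes[i] for i in rng.permutation(len(nodes))]

    if design.ppi_m == 0 or len(order) <= design.ppi_m:
        graph: nx.Graph = nx.Graph()
        graph.add_nodes_from(order)
    else:
        backbone = nx.barabasi_albert_graph(
            len(order), design.ppi_m,
            seed=int(rng.integers(0, 2**31 - 1)))
        graph = nx.relabel_nodes(backbone, dict(enumerate(order)))

    mod = sorted(module)
    for i in range(len(mod)):
        for j in range(i + 1, len(mod)):
            if rng.random() < design.module_edge_prob:
                graph.add_edge(mod[i], mod[j])
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph


def generate_catalog(design: SyntheticDesign, collection: str = "kegg_like"):
    """Annotation catalog over the gene universe.

    The KEGG-like collection holds ``n_pathways`` categories (38 by default)
    the first of which is exactly the planted module; the GO-like collection
    holds ``n_go_terms`` categories, the first again equal to the planted
    module so term-level recovery is testable.  Category sizes are uniform in
    ``category_size_range``.
    """
    from foldnet.enrichment import AnnotationCatalog

    if collection not in ("kegg_like", "go_like"):
        raise ValueError(f"unknown collection {collection!r}")
    truth = plant(design)
    stream = "catalog_kegg" if collection == "kegg_like" else "catalog_go"
    rng = _rng(design.seed, stream)
    n_cat = design.n_pathways if collection == "kegg_like" else design.n_go_terms
    prefix = design.planted_module[:2] if collection == "kegg_like" else "GO"
    lo, hi = design.category_size_range
    universe = design.universe

    categories: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    categories[design.planted_module if collection == "kegg_like" else "GO0001"] = \
        sorted(truth.module_genes)
    for i in range(2, n_cat + 1):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(design.n_genes, size=size, replace=False)
        cid = f"{prefix}{i:04d}" if collection == "go_like" else f"{prefix}{i:02d}"
        categories[cid] = sorted(universe[j] for j in sorted(idx))
    for cid in categories:
        names[cid] = f"synthetic category {cid}"
    return AnnotationCatalog(categories, universe=design.universe,
                             collection=collection, names=names)


def generate_qpcr_plate(
    truth: SyntheticTruth,
    genes: Sequence[str],
    references: Sequence[str],
    conditions: Sequence[str],
    control_sample: str = "control",
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """CT plate whose comparative-CT analysis recovers planted ratios.

    Each gene gets a baseline CT; in a knockdown sample the CT shifts by
    ``-log2(planted ratio)`` (fewer cycles = more template).  Reference genes
    are unplanted by construction, so their CTs agree across samples and the
    geometric-mean normalizer cancels in the delta-delta-CT difference.
    At ``noise_sd = 0`` the recovery is exact.
    """
    if len(references) < 1:
        raise ValueError("at least one reference gene required")
    rng = np.random.default_rng([int(seed), _STREAMS["qpcr"]])
    all_genes = list(dict.fromkeys(list(genes) + list(references)))
    base = {g: 18.0 + 10.0 * rng.random() for g in all_genes}
    samples = [control_sample] + [c for c in conditions if c != control_sample]
    rows = []
    for sample in samples:
        for gene in all_genes:
            if sample == control_sample or gene in references:
                shift = 0.0
            else:
                shift = -float(np.log2(truth.ratio(gene, sample)))
            for rep in range(1, n_replicates + 1):
                ct = base[gene] + shift + rng.normal(0.0, noise_sd)
                rows.append((sample, gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
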