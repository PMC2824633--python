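"""Interactome neighborhood expansion and the empirical random-network null.

``expand_depth1plus`` grows a seed gene set to its immediate interactors and
keeps every interactome edge among the grown node set (seed-seed,
seed-interactor and interactor-interactor alike).  A category's network-level
signal is the proportion of network nodes annotated to it; its significance
is assessed against an ensemble of networks expanded from random seed sets of
the same matched-seed count, via a one-sample Student t comparison with
Bonferroni adjustment across the tested pathway collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from foldnet.enrichment import AnnotationCatalog

__all__ = [
    "ExpandedNetwork",
    "NullEnsemble",
    "expand_depth1plus",
    "network_proportion",
    "build_null",
    "net_enrich_test",
]


@dataclass(frozen=True)
class ExpandedNetwork:
    """Seed + first-neighbor subnetwork of an interactome.

    ``nodes = matched_seeds | interactors``; every interactor is adjacent to a
    matched seed in the source graph; ``edges`` are exactly the source-graph
    edges with both endpoints in ``nodes``.  Unmatched seeds (absent from the
    interactome) are carried for reporting but take no part in proportions.
    """

    matched_seeds: frozenset[str]
    unmatched_seeds: frozenset[str]
    interactors: frozenset[str]
    edges: frozenset[tuple[str, str]]
    components: tuple[frozenset[str], ...]

    @property
    def nodes(self) -> frozenset[str]:
        return self.matched_seeds | self.interactors

    def role(self, node: str) -> str:
        return "seed" if node in self.matched_seeds else "interactor"


def neighborhoods(graph: nx.Graph) -> dict[str, set[str]]:
    """Adjacency sets, excluding self (fast path for repeated expansion)."""
    return {v: set(graph.adj[v]) - {v} for v in graph.nodes}


def _expanded_nodes(adj: Mapping[str, set[str]], matched: set[str]) -> set[str]:
    nodes = set(matched)
    for s in matched:
        nodes |= adj[s]
    return nodes


def expand_depth1plus(graph: nx.Graph, seeds: Iterable[str]) -> ExpandedNetwork:
    """Expand ``seeds`` to depth 1 plus: seeds, their immediate interactors,
    and all interactome edges inside that node set.

    Seeds absent from the graph are recorded as unmatched.  Raises on an
    empty graph.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty interactome graph")
    seeds = set(seeds)
    matched = seeds & set(graph.nodes)
    unmatched = seeds - matched
    adj = {v: set(graph.adj[v]) - {v} for v in matched}
    nodes = set(matched)
    for s in matched:
        nodes |= adj[s]
    sub = graph.subgraph(nodes)
    edges = frozenset(tuple(sorted(e)) for e in sub.edges() if e[0] != e[1])
    components = tuple(frozenset(c) for c in nx.connected_components(sub))
    return ExpandedNetwork(
        matched_seeds=frozenset(matched),
        unmatched_seeds=frozenset(unmatched),
        interactors=frozenset(nodes - matched),
        edges=edges,
        components=components,
    )


def network_proportion(net: ExpandedNetwork | Iterable[str],
                       category: Iterable[str]) -> float:
    """Fraction of network nodes annotated to ``category``."""
    nodes = net.nodes if isinstance(net, ExpandedNetwork) else set(net)
    if not nodes:
        raise ValueError("empty network")
    category = set(category)
    return len(nodes & category) / len(nodes)


@dataclass(frozen=True)
class NullEnsemble:
    """Per-category annotation proportions of R random size-matched networks.

    Each replicate draws exactly ``seed_size`` distinct seeds uniformly from
    ``pool`` (genes on the platform that are present in the interactome),
    expands them depth-1-plus, and records the annotation proportion for
    every catalog category.  ``proportions`` has shape (R, n_categories).
    """

    seed_size: int
    R: int
    pool: tuple[str, ...]
    category_ids: tuple[str, ...]
    proportions: np.ndarray
    seed: int


def build_null(graph: nx.Graph, pool: Sequence[str], s: int, R: int,
               catalog: AnnotationCatalog, seed: int = 0) -> NullEnsemble:
    """Empirical null ensemble of R random depth-1-plus networks of seed size s."""
    pool = sorted(set(pool) & set(graph.nodes))
    if s > len(pool):
        raise ValueError(f"seed size {s} exceeds pool size {len(pool)}")
    if R < 2:
        raise ValueError("R must be >= 2")
    adj = neighborhoods(graph)
    cats = [(cid, catalog.categories[cid]) for cid in catalog.category_ids]
    rng = np.random.default_rng(seed)
    props = np.empty((R, len(cats)))
    pool_arr = np.array(pool, dtype=object)
    for r in range(R):
        picked = pool_arr[rng.choice(len(pool), size=s, replace=False)]
        nodes = _expanded_nodes(adj, set(picked))
        size = len(nodes)
        props[r] = [len(nodes & members) / size for _, members in cats]
    return NullEnsemble(
        seed_size=s, R=R, pool=tuple(pool),
        category_ids=tuple(cid for cid, _ in cats),
        proportions=props, seed=seed,
    )


def net_enrich_test(net: ExpandedNetwork, ensemble: NullEnsemble,
                    catalog: AnnotationCatalog,
                    collection_size: int | None = None,
                    form: str = "t") -> pd.DataFrame:
    """Compare observed annotation proportions against the null ensemble.

    For each category: ``t = (observed - null mean) / (null SD * sqrt(1 + 1/R))``
    with a one-sided p from the t distribution on R-1 degrees of freedom (the
    sqrt(1+1/R) factor is the prediction-interval inflation for comparing one
    new observation against a null sample; ``form="z"`` gives the plain
    (observed-mean)/SD normal form).  An empirical percentile
    ``(1 + #{null >= observed}) / (R + 1)`` is reported alongside, and
    Bonferroni adjustment is applied across the tested collection.

    Degenerate categories (null SD = 0) are flagged: p = 1 if the observed
    proportion does not exceed the null mean, else the empirical floor
    ``1 / (R + 1)``.
    """
    if form not in ("t", "z"):
        raise ValueError("form must be 't' or 'z'")
    R = ensemble.R
    nodes = net.nodes
    if not nodes:
        raise ValueError("empty observed network")
    size = collection_size if collection_size is not None else len(ensemble.category_ids)
    rows = []
    for j, cid in enumerate(ensemble.category_ids):
        observed = len(nodes & catalog.categories[cid]) / len(nodes)
        null = ensemble.proportions[:, j]
        mean, sd = float(null.mean()), float(null.std(ddof=1))
        emp = float((1 + (null >= observed).sum()) / (R + 1))
        degenerate = sd <= 1e-12  # constant null (up to float accumulation)
        if degenerate:
            tstat = np.nan
            p = 1.0 if observed <= mean else 1.0 / (R + 1)
        elif form == "t":
            tstat = (observed - mean) / (sd * np.sqrt(1.0 + 1.0 / R))
            p = float(stats.t.sf(tstat, df=R - 1))
        else:
            tstat = (observed - mean) / sd
            p = float(stats.norm.sf(tstat))
        rows.append((cid, catalog.names.get(cid, cid), observed, mean, sd,
                     tstat, p, emp, min(1.0, p * size), degenerate))
    df = pd.DataFrame(rows, columns=[
        "category", "name", "observed", "null_mean", "null_sd",
        "t", "p", "empirical_p", "adjusted_p", "degenerate"])
    return df.sort_values("adjusted_p", kind="mergesort").reset_index(drop=True)


def write_network(net: ExpandedNetwork, catalog: AnnotationCatalog | None,
                  nodes_path: str | Path, edges_path: str | Path,
                  annotations: Mapping[str, str] | None = None) -> None:
    """Node/edge TSVs importable by graph viewers.

    Unmatched seeds appear in the node table with role ``unmatched_seed`` and
    component ``-1``.  ``annotations`` optionally maps node -> label (e.g.
    up/down direction).
    """
    comp_of = {}
    for i, comp in enumerate(net.components):
        for node in comp:
            comp_of[node] = i
    cat_of: dict[str, list[str]] = {}
    if catalog is not None:
        for cid, members in catalog.categories.items():
            for gene in members:
                cat_of.setdefault(gene, []).append(cid)
    annotations = annotations or {}
    with open(nodes_path, "w") as handle:
        handle.write("node\trole\tcomponent\tlabel\tcategories\n")
        for node in sorted(net.nodes):
            handle.write("\t".join([
                node, net.role(node), str(comp_of.get(node, -1)),
                annotations.get(node, ""), ",".join(sorted(cat_of.get(node, []))),
            ]) + "\n")
        for node in sorted(net.unmatched_seeds):
            handle.write(f"{node}\tunmatched_seed\t-1\t{annotations.get(node, '')}\t\n")
    with open(edges_path, "w") as handle:
        handle.write("node_a\tnode_b\n")
        for a, b in sorted(net.edges):
            handle.write(f"{a}\t{b}\n")
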