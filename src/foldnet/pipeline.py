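"""End-to-end orchestration: filter -> partition -> enrichment -> network null.

Stages communicate only through files, so each is independently re-runnable;
a manifest records package version, seed, input checksums and per-stage row
counts.  Re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from scipy import stats

import foldnet
from foldnet import degs, enrichment, io as fio, ppinet

_KNOWN_KEYS = {
    "expression", "probe_map", "graph", "go_catalog", "kegg_catalog",
    "pool", "universe", "threshold", "fdr_randomizations",
    "null_replicates", "alpha", "seed", "out_dir", "test_form",
}


@dataclass
class RunConfig:
    """Paths and parameters of one full pipeline run."""

    expression: str
    probe_map: str
    graph: str
    go_catalog: str
    kegg_catalog: str
    out_dir: str
    pool: str | None = None        # defaults to universe ∩ graph nodes
    universe: str | None = None    # defaults to genes in the probe map
    threshold: float = 2.0
    fdr_randomizations: int = 1000
    null_replicates: int = 1000
    alpha: float = 0.05
    seed: int = 0
    test_form: str = "t"
    _path_fields = ("expression", "probe_map", "graph", "go_catalog",
                    "kegg_catalog", "pool", "universe")

    def __post_init__(self) -> None:
        if self.threshold <= 1:
            raise ValueError("threshold must be > 1")
        if self.fdr_randomizations < 1 or self.null_replicates < 2:
            raise ValueError("randomization counts too small")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in self._path_fields:
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: no such file {value!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "foldnet",
        "version": foldnet.__version__,
        "seed": config.seed,
        "inputs": {},
        "stages": {},
    }
    for name in RunConfig._path_fields:
        value = getattr(config, name)
        if value is not None:
            manifest["inputs"][name] = {"path": str(value),
                                        "sha256": fio.sha256_file(value)}

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {"elapsed_s": round(time.perf_counter() - t0, 3),
                                        **counts}
            log(f"[{name}] " + " ".join(f"{k}={v}" for k, v in counts.items()))
        return done

    try:
        done = stage("degs")
        table = fio.read_expression(config.expression)
        probe_map = fio.read_probe_map(config.probe_map)
        dsets = degs.call_deregulated(table, probe_map, config.threshold)
        if dsets.partition is None:
            raise ValueError("pipeline requires at least two conditions")
        part = dsets.partition
        degs.write_partition_table(part, out / "partition.tsv")
        gene_sets = {
            f"unique_{part.condition_a}": set(part.unique_a["gene_id"]),
            f"unique_{part.condition_b}": set(part.unique_b["gene_id"]),
            "common": set(part.common["gene_id"]),
        }
        for label, genes in gene_sets.items():
            fio.write_gene_list(sorted(genes), out / f"genes_{label}.txt")
        done(**{k: len(v) for k, v in gene_sets.items()})
    except Exception as exc:
        raise RuntimeError(f"stage degs failed on {config.expression}: {exc}") from exc

    universe = (set(fio.read_gene_list(config.universe)) if config.universe
                else set(probe_map["gene_id"]))
    go_cat = enrichment.AnnotationCatalog.from_gmt(
        config.go_catalog, universe, collection="go_like")
    kegg_cat = enrichment.AnnotationCatalog.from_gmt(
        config.kegg_catalog, universe, collection="kegg_like")

    try:
        done = stage("enrichment")
        counts = {}
        for label, genes in gene_sets.items():
            if not genes:
                counts[label] = 0
                continue
            go_df = enrichment.randomization_fdr(
                genes, go_cat, R=config.fdr_randomizations, seed=config.seed)
            enrichment.write_enrichment(go_df, out / f"enrich_go_{label}.tsv")
            kegg_df = enrichment.kegg_collection_test(genes, kegg_cat)
            enrichment.write_enrichment(kegg_df, out / f"enrich_kegg_{label}.tsv")
            counts[label] = int((kegg_df["adjusted_p"] <= config.alpha).sum())
        done(**{f"sig_{k}": v for k, v in counts.items()})
    except Exception as exc:
        raise RuntimeError(f"stage enrichment failed: {exc}") from exc

    try:
        done = stage("ppinet")
        graph = fio.read_edge_list(config.graph)
        pool = (fio.read_gene_list(config.pool) if config.pool
                else sorted(universe & set(graph.nodes)))
        counts = {}
        for label, genes in gene_sets.items():
            if not genes:
                continue
            net = ppinet.expand_depth1plus(graph, genes)
            ppinet.write_network(net, kegg_cat,
                                 out / f"network_{label}_nodes.tsv",
                                 out / f"network_{label}_edges.tsv")
            s = len(net.matched_seeds)
            if s == 0 or s > len(pool):
                counts[label] = "skipped"
                continue
            ensemble = ppinet.build_null(
                graph, pool, s=s, R=config.null_replicates,
                catalog=kegg_cat, seed=config.seed)
            res = ppinet.net_enrich_test(net, ensemble, kegg_cat,
                                         form=config.test_form)
            res.to_csv(out / f"net_enrich_{label}.tsv", sep="\t",
                       index=False, float_format="%.6g")
            counts[label] = int((res["adjusted_p"] <= config.alpha).sum())
        done(**{f"sig_{k}": v for k, v in counts.items()})
    except Exception as exc:
        raise RuntimeError(f"stage ppinet failed on {config.graph}: {exc}") from exc

    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest


def compare_platforms(array_fc: pd.DataFrame, qpcr_fc: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side per-gene fold changes from two platforms.

    Inputs are frames with columns ``gene`` (or ``gene_id``) and
    ``fold_change``.  Returns one row per shared gene with both fold changes
    and their log2 difference; Spearman rank concordance across shared genes
    is stored in ``df.attrs["rank_concordance"]``.
    """
    import numpy as np

    def norm(df, suffix):
        df = df.rename(columns={"gene_id": "gene"})
        return df[["gene", "fold_change"]].rename(
            columns={"fold_change": f"fold_change_{suffix}"})

    merged = norm(array_fc, "array").merge(norm(qpcr_fc, "qpcr"), on="gene")
    if merged.empty:
        raise ValueError("no shared genes between platforms")
    merged["log2_difference"] = np.log2(
        merged["fold_change_array"] / merged["fold_change_qpcr"])
    if len(merged) > 1:
        rho = stats.spearmanr(merged["fold_change_array"],
                              merged["fold_change_qpcr"]).statistic
    else:
        rho = 1.0
    merged.attrs["rank_concordance"] = float(rho)
    return merged
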