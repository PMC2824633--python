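"""Category over-representation for gene sets.

Given ``k`` changed genes annotated to a category of ``m`` universe members,
with ``n`` changed genes out of an ``N``-gene universe:

* enrichment ratio = ``(k/n) / (m/N)`` — the proportion of changed genes in
  the category relative to the proportion expected from the whole universe;
* significance = one-sided Fisher's exact test, i.e. the upper hypergeometric
  tail ``P(X >= k)`` with ``X ~ Hypergeom(N, m, n)`` (over-representation
  only; depletion is out of scope);
* GO-like catalogs get a randomization FDR: random gene sets of size ``n``
  are redrawn from the universe and category-level p-value exceedances are
  recounted; FDR(c) = mean null count of p-values <= p(c), divided by the
  observed count, clipped to [0, 1] and monotonized in p.  Ties count
  inclusively;
* KEGG-like fixed collections get Bonferroni adjustment across the collection
  (38 pathways by default).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from foldnet import io as fio

__all__ = ["AnnotationCatalog", "fisher_enrich", "randomization_fdr",
           "kegg_collection_test"]


class AnnotationCatalog:
    """Named gene categories over a background universe.

    Members outside the universe are dropped at construction (their count is
    kept in ``n_outside``); category ids must be unique and input member sets
    non-empty.  ``collection`` tags the catalog ``go_like`` or ``kegg_like``.
    """

    def __init__(self, categories: Mapping[str, Iterable[str]],
                 universe: Iterable[str], collection: str = "go_like",
                 names: Mapping[str, str] | None = None) -> None:
        if collection not in ("go_like", "kegg_like"):
            raise ValueError(f"collection must be go_like or kegg_like, got {collection!r}")
        self.universe = frozenset(universe)
        if not self.universe:
            raise ValueError("empty universe")
        self.collection = collection
        self.names = dict(names or {})
        self.categories: dict[str, frozenset[str]] = {}
        self.n_outside = 0
        seen = set()
        for cid, members in categories.items():
            if cid in seen:
                raise ValueError(f"duplicate category id {cid!r}")
            seen.add(cid)
            members = set(members)
            if not members:
                raise ValueError(f"category {cid!r} has no members")
            inside = members & self.universe
            self.n_outside += len(members) - len(inside)
            self.categories[cid] = frozenset(inside)
        # stable gene ordering for the membership matrix
        self._genes = sorted(self.universe)
        self._gene_index = {g: i for i, g in enumerate(self._genes)}

    def __len__(self) -> int:
        return len(self.categories)

    @property
    def category_ids(self) -> list[str]:
        return list(self.categories)

    def membership_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Boolean matrix (categories x universe genes) and the row ids."""
        cids = self.category_ids
        mat = np.zeros((len(cids), len(self._genes)), dtype=bool)
        for row, cid in enumerate(cids):
            for gene in self.categories[cid]:
                mat[row, self._gene_index[gene]] = True
        return mat, cids

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        return np.array(sorted(self._gene_index[g] for g in genes), dtype=int)

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str],
                 collection: str = "go_like") -> "AnnotationCatalog":
        categories, names = fio.read_gmt(path)
        return cls(categories, universe, collection=collection, names=names)

    def to_gmt(self, path: str | Path) -> None:
        fio.write_gmt(self.categories, self.names, path)


def _clean_changed(changed: Iterable[str], catalog: AnnotationCatalog) -> set[str]:
    changed = set(changed)
    if not changed:
        raise ValueError("empty changed gene set")
    inside = changed & catalog.universe
    if not inside:
        raise ValueError("no changed genes inside the catalog universe")
    return inside


def _tail_p(k: np.ndarray, m: np.ndarray, n: int, N: int) -> np.ndarray:
    # upper tail P(X >= k), X ~ Hypergeom(N, m, n)
    return stats.hypergeom.sf(np.asarray(k) - 1, N, m, n)


def fisher_enrich(changed: Iterable[str], catalog: AnnotationCatalog) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation test per category.

    Changed genes outside the universe are dropped (count in attribute
    ``df.attrs["n_dropped"]``).  Categories empty within the universe are
    skipped.  Returns columns ``category, name, k, m, n, N, enrichment, p``
    sorted by p.
    """
    original = set(changed)
    inside = _clean_changed(original, catalog)
    N = len(catalog.universe)
    n = len(inside)
    rows = []
    for cid, members in catalog.categories.items():
        m = len(members)
        if m == 0:
            continue
        k = len(members & inside)
        enr = (k / n) / (m / N)
        p = float(_tail_p(np.array([k]), np.array([m]), n, N)[0])
        rows.append((cid, catalog.names.get(cid, cid), k, m, n, N, enr, p))
    df = pd.DataFrame(
        rows, columns=["category", "name", "k", "m", "n", "N", "enrichment", "p"])
    df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    df.attrs["n_dropped"] = len(original) - len(inside)
    return df


def randomization_fdr(changed: Iterable[str], catalog: AnnotationCatalog,
                      R: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Fisher enrichment plus a randomization FDR column.

    For each of ``R`` randomizations, ``n`` genes are drawn uniformly without
    replacement from the universe and all category p-values recomputed.
    ``FDR(c) = mean_r #{null p <= p(c)} / max(1, #{observed p <= p(c)})``,
    clipped to [0, 1] and made monotone non-decreasing in p.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    obs = fisher_enrich(changed, catalog)
    inside = _clean_changed(set(changed), catalog)
    N = len(catalog.universe)
    n = len(inside)
    mat, cids = catalog.membership_matrix()
    keep = [i for i, cid in enumerate(cids) if cid in set(obs["category"])]
    mat = mat[keep]
    m_vec = mat.sum(axis=1)

    # p depends only on k for fixed (m, n, N): precompute lookup rows
    tables = [
        _tail_p(np.arange(min(int(m), n) + 1), np.full(min(int(m), n) + 1, int(m)), n, N)
        for m in m_vec
    ]
    rng = np.random.default_rng(seed)
    null_ps = np.empty((R, len(m_vec)))
    for r in range(R):
        idx = rng.choice(N, size=n, replace=False)
        k = mat[:, idx].sum(axis=1)
        null_ps[r] = [tables[c][k[c]] for c in range(len(m_vec))]

    null_sorted = np.sort(null_ps.ravel())
    p_obs = obs["p"].to_numpy()
    mean_null_exceed = np.searchsorted(null_sorted, p_obs, side="right") / R
    obs_exceed = np.array([(p_obs <= p).sum() for p in p_obs])
    fdr = np.clip(mean_null_exceed / np.maximum(1, obs_exceed), 0.0, 1.0)
    # obs already sorted by p; enforce monotonicity in p
    fdr = np.maximum.accumulate(fdr)
    out = obs.copy()
    out["fdr"] = fdr
    return out


def kegg_collection_test(changed: Iterable[str], catalog: AnnotationCatalog,
                         collection_size: int | None = None) -> pd.DataFrame:
    """Fisher test over a fixed pathway collection with Bonferroni adjustment.

    ``adjusted_p = min(1, p * collection_size)`` where the collection size
    defaults to the number of categories in the catalog (38 for the default
    pathway collection).
    """
    if catalog.collection != "kegg_like":
        raise ValueError("kegg_collection_test requires a kegg_like catalog")
    df = fisher_enrich(changed, catalog)
    size = collection_size if collection_size is not None else len(df)
    df["adjusted_p"] = np.clip(df["p"] * size, 0.0, 1.0)
    return df


def write_enrichment(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
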