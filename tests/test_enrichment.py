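import itertools
import math

import numpy as np
import pandas as pd
import pytest

from foldnet import synthetic
from foldnet.enrichment import (AnnotationCatalog, fisher_enrich,
                                kegg_collection_test, randomization_fdr)


def catalog_of(categories, universe, collection="go_like"):
    return AnnotationCatalog(categories, universe, collection=collection)


def brute_force_tail_p(N, m, n, k):
    """P(|S ∩ category| >= k) by enumerating all C(N, n) draws."""
    universe = range(N)
    category = set(range(m))
    total = hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(category & set(draw)) >= k:
            hits += 1
    return hits / total


class TestFisher:
    def test_exact_small_example(self):
        # N=10, m=4, n=3, k=3: C(4,3)*C(6,0)/C(10,3) = 4/120
        universe = [f"g{i}" for i in range(10)]
        cat = catalog_of({"c": universe[:4]}, universe)
        df = fisher_enrich(set(universe[:3]), cat)
        assert df["k"].iloc[0] == 3
        assert df["p"].iloc[0] == pytest.approx(4 / 120)
        assert df["p"].iloc[0] == pytest.approx(brute_force_tail_p(10, 4, 3, 3))

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        cat = catalog_of({"c": universe[:4]}, universe)
        df = fisher_enrich(set(universe[6:9]), cat)
        assert df["k"].iloc[0] == 0
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_category_equal_to_universe(self):
        universe = [f"g{i}" for i in range(8)]
        cat = catalog_of({"c": universe}, universe)
        df = fisher_enrich(set(universe[:3]), cat)
        assert df["enrichment"].iloc[0] == pytest.approx(1.0)
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_changed_set_errors(self):
        cat = catalog_of({"c": ["g0"]}, ["g0", "g1"])
        with pytest.raises(ValueError, match="empty changed"):
            fisher_enrich(set(), cat)

    def test_changed_outside_universe_dropped_and_counted(self):
        universe = [f"g{i}" for i in range(10)]
        cat = catalog_of({"c": universe[:4]}, universe)
        df = fisher_enrich({"g0", "g1", "not_a_gene"}, cat)
        assert df["n"].iloc[0] == 2
        assert df.attrs["n_dropped"] == 1

    def test_category_empty_in_universe_skipped(self):
        universe = [f"g{i}" for i in range(10)]
        cat = catalog_of({"inside": universe[:3], "outside": ["x1", "x2"]}, universe)
        df = fisher_enrich({"g0"}, cat)
        assert set(df["category"]) == {"inside"}

    def test_enrichment_above_one_iff_overrepresented(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(50)]
        cat = catalog_of(
            {f"c{j}": list(rng.choice(universe, 12, replace=False)) for j in range(8)},
            universe)
        df = fisher_enrich(set(rng.choice(universe, 15, replace=False)), cat)
        for _, row in df.iterrows():
            lhs = row["enrichment"] > 1
            rhs = row["k"] / row["n"] > row["m"] / row["N"]
            assert lhs == rhs

    def test_p_nonincreasing_in_k(self):
        from foldnet.enrichment import _tail_p
        N, m, n = 40, 10, 8
        ps = [_tail_p(np.array([k]), np.array([m]), n, N)[0] for k in range(n + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_exhaustive_oracle_medium(self):
        from foldnet.enrichment import _tail_p
        for N in (5, 8):
            for m in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(0, min(m, n) + 1):
                        assert _tail_p(np.array([k]), np.array([m]), n, N)[0] == \
                            pytest.approx(brute_force_tail_p(N, m, n, k))


class TestCatalog:
    def test_duplicate_ids_rejected_via_gmt(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("c1\tdesc\tg0\tg1\nc1\tdesc\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            AnnotationCatalog.from_gmt(path, ["g0", "g1", "g2"])

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            catalog_of({"c": []}, ["g0"])

    def test_invalid_collection_tag(self):
        with pytest.raises(ValueError, match="collection"):
            catalog_of({"c": ["g0"]}, ["g0"], collection="other")

    def test_membership_matrix_partition_row_sums(self):
        universe = [f"g{i}" for i in range(12)]
        cat = catalog_of({"a": universe[:4], "b": universe[4:8], "c": universe[8:]},
                         universe)
        mat, _ = cat.membership_matrix()
        assert (mat.sum(axis=0) == 1).all()

    def test_gmt_round_trip(self, tmp_path, small_data):
        kegg = small_data["kegg"]
        path = tmp_path / "kegg.gmt"
        kegg.to_gmt(path)
        back = AnnotationCatalog.from_gmt(
            path, small_data["design"].universe, collection="kegg_like")
        assert back.categories == kegg.categories


class TestRandomizationFdr:
    def test_deterministic_given_seed(self):
        universe = [f"g{i}" for i in range(60)]
        rng = np.random.default_rng(5)
        cat = catalog_of(
            {f"c{j}": list(rng.choice(universe, 10, replace=False)) for j in range(6)},
            universe)
        changed = set(universe[:12])
        a = randomization_fdr(changed, cat, R=1, seed=3)
        b = randomization_fdr(changed, cat, R=1, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_extreme_signal_fdr_goes_to_zero(self):
        universe = [f"g{i}" for i in range(400)]
        rng = np.random.default_rng(6)
        categories = {"signal": universe[:15]}
        for j in range(20):
            categories[f"c{j}"] = list(rng.choice(universe, 20, replace=False))
        cat = catalog_of(categories, universe)
        df = randomization_fdr(set(universe[:15]), cat, R=500, seed=0)
        assert df.set_index("category").loc["signal", "fdr"] < 0.01

    def test_fdr_monotone_in_p(self, small_data):
        df = randomization_fdr(set(small_data["truth"].planted("kd1")),
                               small_data["go"], R=100, seed=1)
        assert df["fdr"].is_monotonic_increasing  # df sorted by p
        assert ((df["fdr"] >= 0) & (df["fdr"] <= 1)).all()

    def test_requires_positive_R(self, small_data):
        with pytest.raises(ValueError, match="R"):
            randomization_fdr({"G0001"}, small_data["go"], R=0)

    def test_null_calibration_smoke(self):
        # no-signal draws should essentially never reach FDR < 0.05
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(300)]
        categories = {f"c{j}": list(rng.choice(universe, 15, replace=False))
                      for j in range(25)}
        cat = catalog_of(categories, universe)
        low = total = 0
        for rep in range(30):
            changed = set(rng.choice(universe, 30, replace=False))
            df = randomization_fdr(changed, cat, R=100, seed=rep)
            low += int((df["fdr"] < 0.05).sum())
            total += len(df)
        assert low / total <= 0.01


class TestCollectionTest:
    def test_bonferroni_arithmetic(self):
        # N=12, m=3, n=3, k=3: p = 1/C(12,3) = 1/220; times 38 = 38/220
        universe = [f"g{i}" for i in range(12)]
        categories = {"hit": universe[:3]}
        rng = np.random.default_rng(8)
        for j in range(37):
            categories[f"c{j}"] = list(rng.choice(universe[3:], 4, replace=False))
        cat = catalog_of(categories, universe, collection="kegg_like")
        df = kegg_collection_test(set(universe[:3]), cat).set_index("category")
        assert df.loc["hit", "p"] == pytest.approx(1 / 220)
        assert df.loc["hit", "adjusted_p"] == pytest.approx(38 / 220)

    def test_adjusted_p_clipped_at_one(self):
        universe = [f"g{i}" for i in range(20)]
        cat = catalog_of({"c": universe[:5], "d": universe[5:10]}, universe,
                         collection="kegg_like")
        df = kegg_collection_test(set(universe[10:15]), cat, collection_size=38)
        assert (df["adjusted_p"] <= 1.0).all()
        assert df["adjusted_p"].max() == pytest.approx(1.0)

    def test_single_pathway_collection_is_identity(self):
        universe = [f"g{i}" for i in range(20)]
        cat = catalog_of({"c": universe[:5]}, universe, collection="kegg_like")
        df = kegg_collection_test(set(universe[:4]), cat)
        assert df["adjusted_p"].iloc[0] == pytest.approx(df["p"].iloc[0])

    def test_requires_kegg_like_catalog(self):
        universe = [f"g{i}" for i in range(10)]
        cat = catalog_of({"c": universe[:4]}, universe, collection="go_like")
        with pytest.raises(ValueError, match="kegg_like"):
            kegg_collection_test(set(universe[:3]), cat)


def test_type_one_error_controlled():
    # under uniform random changed sets the Fisher p is (conservatively) valid
    rng = np.random.default_rng(9)
    universe = [f"g{i}" for i in range(200)]
    categories = {f"c{j}": list(rng.choice(universe, 20, replace=False))
                  for j in range(30)}
    cat = catalog_of(categories, universe)
    reps = 100
    for alpha in (0.01, 0.05):
        exceed = 0
        total = 0
        rng2 = np.random.default_rng(10)
        for _ in range(reps):
            changed = set(rng2.choice(universe, 25, replace=False))
            df = fisher_enrich(changed, cat)
            exceed += int((df["p"] <= alpha).sum())
            total += len(df)
        sd = math.sqrt(alpha * (1 - alpha) / reps)
        assert exceed / total <= alpha + 3 * sd


def test_planted_category_power(small_design):
    # planted module genes are inside the recovered changed set, so the
    # matching category must reach FDR < 0.05 in nearly all replicates
    from foldnet import degs
    hits = 0
    reps = 50
    for rep in range(reps):
        design = synthetic.SyntheticDesign(
            **{**{k: v for k, v in small_design.__dict__.items()
                  if not k.startswith("_")}, "noise_sd": 0.1, "seed": 100 + rep})
        table, pmap, truth = synthetic.generate_expression(design)
        changed = degs.call_deregulated(table, pmap, 2.0).genes("kd1")
        go = synthetic.generate_catalog(design, "go_like")
        df = randomization_fdr(changed, go, R=100, seed=rep).set_index("category")
        if df.loc["GO0001", "fdr"] < 0.05:
            hits += 1
    assert hits >= int(0.95 * reps)
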