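import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from sibmicro import (FeatureTable, permanova, betadisper,
                      welch_distance_ttest, top_taxa, diff_abundance,
                      dunn_posthoc, bh_fdr, bray_curtis)
import oracles


def euclid_dm(points, ids=None):
    d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(d, ids=ids)


def design_of(dm, **cols):
    return pd.DataFrame(cols, index=list(dm.ids))


class TestPermanova:
    def test_variance_partition_identity(self, rng):
        pts = rng.normal(size=(12, 3))
        dm = euclid_dm(pts)
        des = design_of(dm, g=np.repeat(["a", "b", "c"], 4),
                        x=rng.normal(size=12))
        res = permanova(dm, des, mode="sequential", n_perm=49, seed=0)
        total = res.terms["r_squared"].sum() + res.residual_r_squared
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_skbio_single_factor_f(self, rng):
        pts = rng.normal(size=(14, 4))
        groups = np.repeat(["a", "b"], 7)
        dm = euclid_dm(pts)
        mine = permanova(dm, design_of(dm, g=groups), n_perm=99, seed=1)
        ref = skbio_permanova(dm, grouping=groups, permutations=99)
        assert mine.terms.loc["g", "F"] == pytest.approx(
            ref["test statistic"], abs=1e-10)

    def test_f_invariant_under_sample_reordering(self, rng):
        pts = rng.normal(size=(10, 2))
        groups = np.array(["a", "b"] * 5)
        dm = euclid_dm(pts)
        res1 = permanova(dm, design_of(dm, g=groups), n_perm=9, seed=0)
        order = rng.permutation(10)
        ids2 = [dm.ids[i] for i in order]
        dm2 = dm.filter(ids2)
        res2 = permanova(dm2, design_of(dm2, g=groups[order]),
                         n_perm=9, seed=0)
        assert res1.terms.loc["g", "F"] == pytest.approx(
            res2.terms.loc["g", "F"], abs=1e-10)

    def test_marginal_mode_adjusts_for_other_terms(self, rng):
        # a term duplicated is fully aliased in marginal mode
        pts = rng.normal(size=(10, 2))
        dm = euclid_dm(pts)
        g = np.repeat(["a", "b"], 5)
        with pytest.raises(ValueError, match="alias"):
            permanova(dm, design_of(dm, g=g, h=g), mode="marginal",
                      n_perm=9, seed=0)

    def test_complete_case_drops_missing(self, rng):
        pts = rng.normal(size=(12, 2))
        dm = euclid_dm(pts)
        x = rng.normal(size=12)
        x[0] = np.nan
        res = permanova(dm, design_of(dm, x=x), n_perm=9, seed=0)
        assert res.n == 11

    def test_pseudo_f_matches_textbook_two_group_formula(self, rng):
        pts = rng.normal(size=(12, 3))
        dm = euclid_dm(pts)
        mask = np.zeros(12, dtype=bool)
        mask[:5] = True
        groups = np.where(mask, "a", "b")
        res = permanova(dm, design_of(dm, g=groups), n_perm=9, seed=0)
        expected = oracles.pseudo_f_two_group(dm.data, mask)
        assert res.terms.loc["g", "F"] == pytest.approx(expected, abs=1e-10)


class TestBetadisper:
    def test_scaled_group_doubles_mean_centroid_distance(self, rng):
        base = rng.normal(size=(30, 3))
        pts = np.vstack([base, 2.0 * rng.normal(size=(30, 3))])
        dm = euclid_dm(pts)
        groups = np.repeat(["a", "b"], 30)
        res = betadisper(dm, groups, n_perm=99, seed=0)
        assert res.group_mean_dist["b"] / res.group_mean_dist["a"] == \
            pytest.approx(2.0, rel=0.25)
        assert res.ratio >= 1.0

    def test_singleton_group_excluded_with_warning(self, rng):
        pts = rng.normal(size=(7, 2))
        dm = euclid_dm(pts)
        groups = ["a", "a", "a", "b", "b", "b", "c"]
        with pytest.warns(UserWarning, match="size-1"):
            res = betadisper(dm, groups, n_perm=9, seed=0)
        assert set(res.group_mean_dist.index) == {"a", "b"}

    def test_equal_dispersion_rarely_rejects(self, rng):
        rejections = 0
        for rep in range(40):
            pts = rng.normal(size=(24, 3))
            dm = euclid_dm(pts)
            groups = np.repeat(["a", "b"], 12)
            res = betadisper(dm, groups, n_perm=99, seed=rep)
            rejections += res.p < 0.05
        assert rejections / 40 <= 0.15


class TestWelchDistance:
    def test_requires_two_groups(self, rng):
        dm = euclid_dm(rng.normal(size=(6, 2)))
        with pytest.raises(ValueError):
            welch_distance_ttest(dm, ["a"] * 6, n_perm=9)

    def test_null_rejection_rate(self, rng):
        rejections = 0
        for rep in range(60):
            pts = rng.normal(size=(20, 3))
            dm = euclid_dm(pts)
            res = welch_distance_ttest(dm, np.repeat(["a", "b"], 10),
                                       n_perm=99, seed=rep)
            rejections += res.p < 0.05
        assert 0.0 <= rejections / 60 <= 0.13

    def test_detects_location_shift(self, rng):
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3)) + 2.0
        dm = euclid_dm(np.vstack([a, b]))
        res = welch_distance_ttest(dm, np.repeat(["a", "b"], 15),
                                   n_perm=199, seed=0)
        assert res.p < 0.01


def toy_table_with_taxonomy():
    counts = pd.DataFrame(
        [[8, 2, 0, 4], [6, 4, 1, 1], [2, 8, 2, 0]],
        index=["s1", "s2", "s3"],
        columns=["asv1", "asv2", "asv3", "asv4"])
    tax = {
        "asv1": ["Bacteria", "p1", "c1", "o1", "f1", "Moraxella"],
        "asv2": ["Bacteria", "p1", "c1", "o1", "f1", "Staphylococcus"],
        "asv3": ["Bacteria", "p1", "c1", "o1", "f2"],   # genus unassigned
        "asv4": ["Bacteria", "p2", "c2", "o2", "f3", "Moraxella"],
    }
    return FeatureTable(counts, taxonomy=tax)


class TestTopTaxa:
    def test_hand_computed_means_and_order(self):
        table = toy_table_with_taxonomy()
        names, agg = top_taxa(table, rank="genus", n=10)
        rel = table.relative_abundance()
        expected_morax = (rel["asv1"] + rel["asv4"]).mean()
        assert agg["Moraxella"].mean() == pytest.approx(expected_morax)
        means = agg.mean(axis=0)
        assert list(means[names]) == sorted(means, reverse=True) or \
            all(means[names[i]] >= means[names[i + 1]] - 1e-12
                for i in range(len(names) - 1))

    def test_unassigned_collapses_to_parent_rank(self):
        _, agg = top_taxa(toy_table_with_taxonomy(), rank="genus", n=10)
        assert "f2 unclassified" in agg.columns

    def test_equal_means_break_lexicographically(self):
        counts = pd.DataFrame([[5, 5], [3, 3]], index=["s1", "s2"],
                              columns=["a1", "a2"])
        tax = {"a1": ["B", "p", "c", "o", "f", "zeta"],
               "a2": ["B", "p", "c", "o", "f", "alpha"]}
        names, _ = top_taxa(FeatureTable(counts, taxonomy=tax),
                            rank="genus", n=2)
        assert names == ["alpha", "zeta"]

    def test_missing_taxonomy_is_an_error(self):
        t = FeatureTable(pd.DataFrame([[1]], index=["s"], columns=["a"]))
        with pytest.raises(ValueError):
            top_taxa(t, rank="genus")


class TestDiffAbundance:
    def test_bh_stepup_by_hand(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_and_bounded(self, rng):
        p = rng.random(30)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1)

    def test_exact_wilcoxon_disjoint_ranges(self):
        vals = pd.DataFrame({"t": np.r_[np.arange(5), np.arange(10, 15)] / 20},
                            index=[f"s{i}" for i in range(10)])
        groups = np.repeat(["a", "b"], 5)
        res = diff_abundance(vals, groups)
        assert res.table.loc["t", "p"] == pytest.approx(2 / 252)
        assert res.table.loc["t", "test"] == "wilcoxon"

    def test_constant_taxon_flagged(self):
        vals = pd.DataFrame({"t": np.ones(8)},
                            index=[f"s{i}" for i in range(8)])
        res = diff_abundance(vals, np.repeat(["a", "b"], 4))
        assert res.table.loc["t", "p"] == 1.0
        assert "constant" in res.table.loc["t", "note"]

    def test_three_groups_use_kruskal(self, rng):
        vals = pd.DataFrame({"t": rng.random(9)},
                            index=[f"s{i}" for i in range(9)])
        res = diff_abundance(vals, np.repeat(["a", "b", "c"], 3))
        assert res.table.loc["t", "test"] == "kruskal"

    def test_null_fdr_control(self, rng):
        false_hits = 0
        for _ in range(100):
            vals = pd.DataFrame(rng.random((20, 8)),
                                index=[f"s{i}" for i in range(20)])
            res = diff_abundance(vals, rng.permutation(
                np.repeat(["a", "b"], 10)))
            false_hits += (res.table["q"] < 0.05).any()
        assert false_hits / 100 <= 0.08


class TestDunn:
    def test_hand_formula_oracle(self):
        vals = np.array([1.0, 2, 3, 10, 11, 12, 20, 21, 22])
        groups = np.repeat(["a", "b", "c"], 3)
        res = dunn_posthoc(vals, groups)
        # mean ranks: a=2, b=5, c=8; no ties; var base = n(n+1)/12
        se = np.sqrt(9 * 10 / 12 * (1 / 3 + 1 / 3))
        row = res[(res.group_a == "a") & (res.group_b == "c")].iloc[0]
        assert row["z"] == pytest.approx((2 - 8) / se)

    def test_shifted_group_detected(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 1, 50)
        c = rng.normal(2.0, 1, 50)
        res = dunn_posthoc(np.r_[a, b, c], np.repeat(["a", "b", "c"], 50))
        sig = res[res.q < 0.05]
        pairs = {frozenset((r.group_a, r.group_b)) for r in sig.itertuples()}
        assert frozenset(("a", "c")) in pairs
        assert frozenset(("b", "c")) in pairs
        assert frozenset(("a", "b")) not in pairs

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            dunn_posthoc([1, 2, 3, 4], ["a", "a", "b", "b"])
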