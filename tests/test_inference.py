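from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from contamscope.diversity import DistanceMatrix
from contamscope.inference import (
    bh_adjust,
    gehan_wilcoxon_test,
    holm_adjust,
    nb_wald_diff_abundance,
    permanova,
    two_way_anova,
    wilcoxon_rank_sum,
)
from contamscope.tables import FeatureTable, SampleMetadata, ValidationError


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def exact_wilcoxon_p(x, y):
    """Enumeration oracle: two-sided p over all rank assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    sums = [sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), n1)]
    dev = abs(obs - mean)
    return np.mean([abs(s - mean) >= dev - 1e-12 for s in sums])


class TestWilcoxon:
    def test_identical_multisets_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_exact_small_sample_example(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_approximation_close_to_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(0.5, size=7)
            p_approx = wilcoxon_rank_sum(x, y, exact_if_small=False)
            assert abs(p_approx - exact_wilcoxon_p(x, y)) < 0.02

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# Multiple-testing adjustment
# ---------------------------------------------------------------------------

class TestAdjustments:
    def test_holm_hand_case(self):
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_bh_hand_case(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @pytest.mark.parametrize("adjust", [holm_adjust, bh_adjust])
    def test_single_p_unchanged_and_cap(self, adjust):
        assert adjust([0.2]) == pytest.approx([0.2])
        assert adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    @pytest.mark.parametrize("adjust,method", [(holm_adjust, "holm"),
                                               (bh_adjust, "fdr_bh")])
    def test_matches_statsmodels(self, adjust, method):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(19)
        for _ in range(25):
            p = rng.random(rng.integers(1, 15))
            ref = multipletests(p, method=method)[1]
            assert adjust(p) == pytest.approx(ref, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, pvals, rnd):
        order = list(range(len(pvals)))
        rnd.shuffle(order)
        shuffled = [pvals[i] for i in order]
        for adjust in (holm_adjust, bh_adjust):
            direct = adjust(pvals)
            via = adjust(shuffled)
            assert [via[order.index(i)] for i in range(len(pvals))] == \
                pytest.approx(list(direct))
        for adjust in (holm_adjust, bh_adjust):
            assert np.all(adjust(pvals) >= np.asarray(pvals) - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([1.2])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def one_factor_pseudo_f(d, labels):
    """Direct within/between SS oracle for a single factor."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_tot = (d**2).sum() / (2 * n)
    ss_within = 0.0
    for lv in set(labels):
        idx = np.where(labels == lv)[0]
        ss_within += (d[np.ix_(idx, idx)] ** 2).sum() / (2 * len(idx))
    a = len(set(labels))
    return ((ss_tot - ss_within) / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_single_group_errors(self):
        d = squareform(pdist(np.random.default_rng(0).normal(size=(4, 2))))
        dm = DistanceMatrix(list("abcd"), d)
        with pytest.raises(ValidationError, match="single level"):
            permanova(dm, {"g": ["x"] * 4}, n_permutations=99)

    @pytest.mark.parametrize("labels", [["a", "a", "b", "b"],
                                        ["a", "a", "a", "b", "b", "b"]])
    def test_exact_enumeration_matches_oracle(self, labels):
        rng = np.random.default_rng(31)
        n = len(labels)
        d = squareform(pdist(rng.normal(size=(n, 2))))
        dm = DistanceMatrix([f"s{i}" for i in range(n)], d)
        res = permanova(dm, {"g": labels}, exact=True)
        f_obs = one_factor_pseudo_f(d, labels)
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(f_obs, rel=1e-9)
        perms = [one_factor_pseudo_f(d, np.asarray(labels)[list(p)])
                 for p in permutations(range(n))]
        p_enum = np.mean([f >= f_obs - 1e-12 for f in perms])
        assert res.table.loc["g", "p_perm"] == pytest.approx(p_enum)

    def test_separated_clouds_reach_minimum_p(self):
        rng = np.random.default_rng(32)
        pts = np.vstack([rng.normal(0, 0.3, size=(10, 2)),
                         rng.normal(5, 0.3, size=(10, 2))])
        d = squareform(pdist(pts))
        dm = DistanceMatrix([f"s{i}" for i in range(20)], d)
        res = permanova(dm, {"g": ["a"] * 10 + ["b"] * 10},
                        n_permutations=999, seed=1)
        assert res.table.loc["g", "p_perm"] == pytest.approx(1 / 1000)

    def test_matches_skbio_pseudo_f(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(33)
        d = squareform(pdist(rng.normal(size=(12, 3))))
        ids = [f"s{i}" for i in range(12)]
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = permanova(DistanceMatrix(ids, d), {"g": labels},
                        n_permutations=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d, ids), labels, permutations=9)
        assert res.table.loc["g", "pseudo_F"] == \
            pytest.approx(ref["test statistic"], rel=1e-9)

    def test_two_factor_ss_partition_is_additive(self):
        rng = np.random.default_rng(34)
        d = squareform(pdist(rng.normal(size=(16, 3))))
        dm = DistanceMatrix([f"s{i}" for i in range(16)], d)
        fa = (["a"] * 8 + ["b"] * 8)
        fb = (["x", "x", "y", "y"] * 4)
        res = permanova(dm, {"A": fa, "B": fb}, include_interaction=True,
                        n_permutations=99, seed=2)
        total = res.table["ss"].sum() + res.ss_residual
        assert total == pytest.approx(res.ss_total, abs=1e-8)

    def test_seeded_runs_are_bit_reproducible(self):
        rng = np.random.default_rng(35)
        d = squareform(pdist(rng.normal(size=(14, 3))))
        dm = DistanceMatrix([f"s{i}" for i in range(14)], d)
        labels = ["a"] * 7 + ["b"] * 7
        r1 = permanova(dm, {"g": labels}, n_permutations=199, seed=11)
        r2 = permanova(dm, {"g": labels}, n_permutations=199, seed=11)
        assert r1.table.equals(r2.table)


# ---------------------------------------------------------------------------
# Two-way ANOVA
# ---------------------------------------------------------------------------

class TestTwoWayAnova:
    def test_pure_main_effect_zeroes_other_terms(self):
        a = np.repeat(["a1", "a2"], 6)
        b = np.tile(["b1", "b2", "b3"], 4)
        y = np.where(a == "a1", 1.0, 3.0)
        tab = two_way_anova(y, a, b)
        assert tab.loc["B", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc["A:B", "ss"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(40)
        a = np.repeat(["a1", "a2"], 8)
        b = np.tile(np.repeat(["b1", "b2"], 4), 2)
        y = rng.normal(size=16) + (a == "a2") * 1.2 + (b == "b2") * 0.4
        tab = two_way_anova(y, a, b)
        # balanced design: Type-I SS equal the classical marginal sums
        grand = y.mean()
        ss_a = sum(len(y[a == lv]) * (y[a == lv].mean() - grand) ** 2
                   for lv in np.unique(a))
        ss_b = sum(len(y[b == lv]) * (y[b == lv].mean() - grand) ** 2
                   for lv in np.unique(b))
        ss_cells = sum(
            (m := y[(a == la) & (b == lb)]).size * (m.mean() - grand) ** 2
            for la in np.unique(a) for lb in np.unique(b))
        assert tab.loc["A", "ss"] == pytest.approx(ss_a)
        assert tab.loc["B", "ss"] == pytest.approx(ss_b)
        assert tab.loc["A:B", "ss"] == pytest.approx(ss_cells - ss_a - ss_b)

    def test_empty_cell_error_names_cell(self):
        a = ["a1", "a1", "a2", "a2", "a2"]
        b = ["b1", "b1", "b1", "b2", "b2"]
        with pytest.raises(ValidationError, match="a1"):
            two_way_anova([1.0, 2, 3, 4, 5], a, b)

    def test_null_interaction_type_i_error_calibrated(self):
        rng = np.random.default_rng(41)
        rej = 0
        n_rep = 400
        a = np.repeat(["a1", "a2", "a3"], 8)
        b = np.tile(np.repeat(["b1", "b2"], 4), 3)
        for _ in range(n_rep):
            y = rng.normal(size=24)
            tab = two_way_anova(y, a, b)
            rej += tab.loc["A:B", "p"] < 0.05
        assert 0.03 <= rej / n_rep <= 0.07


# ---------------------------------------------------------------------------
# NB Wald differential abundance
# ---------------------------------------------------------------------------

def _two_group_md(n):
    samples = [f"s{j}" for j in range(2 * n)]
    return samples, SampleMetadata(pd.DataFrame(
        {"role": "specimen", "replicate": "r1",
         "grp": ["A"] * n + ["B"] * n}, index=samples))


class TestNbWald:
    def test_symmetric_input_gives_zero_fold_change(self):
        rng = np.random.default_rng(50)
        half = rng.integers(1, 100, size=(10, 6))
        counts = np.hstack([half, half])
        samples, md = _two_group_md(6)
        ft = FeatureTable(pd.DataFrame(
            counts, index=[f"g{i}" for i in range(10)], columns=samples))
        res = nb_wald_diff_abundance(ft, md, ("grp", "A", "B"))
        assert np.allclose(res.table["log2_fc"], 0.0, atol=1e-8)
        assert np.all(np.sign(res.table["log2_fc"]) ==
                      np.sign(res.table["wald_z"]))

    def test_one_sided_genus_is_boundary_with_finite_fc(self):
        rng = np.random.default_rng(51)
        counts = rng.integers(5, 50, size=(6, 12))
        counts[0, 6:] = 0  # present only in group A
        samples, md = _two_group_md(6)
        ft = FeatureTable(pd.DataFrame(
            counts, index=[f"g{i}" for i in range(6)], columns=samples))
        res = nb_wald_diff_abundance(ft, md, ("grp", "A", "B"))
        row = res.table.loc["g0"]
        assert row["boundary"]
        assert np.isfinite(row["log2_fc"]) and row["log2_fc"] < 0
        assert res.table["padj"].min() >= 0
        assert (res.table["padj"] >= res.table["p"] - 1e-15).all()

    def test_all_zero_genus_dropped_and_missing_level_errors(self):
        counts = np.ones((3, 8), dtype=int)
        counts[1] = 0
        samples, md = _two_group_md(4)
        ft = FeatureTable(pd.DataFrame(
            counts, index=["g0", "g1", "g2"], columns=samples))
        res = nb_wald_diff_abundance(ft, md, ("grp", "A", "B"))
        assert res.dropped == ["g1"]
        with pytest.raises(ValidationError, match="fewer than 2"):
            nb_wald_diff_abundance(ft, md, ("grp", "A", "C"))

    def test_recovers_planted_ratio_with_unit_size_factors(self):
        rng = np.random.default_rng(52)
        n, n_gen, r = 20, 60, 10.0
        mu = rng.uniform(20, 200, n_gen)
        counts = np.zeros((n_gen, 2 * n), dtype=int)
        for gi in range(n_gen):
            counts[gi, :n] = rng.negative_binomial(r, r / (r + mu[gi]), n)
            counts[gi, n:] = rng.negative_binomial(r, r / (r + 4 * mu[gi]), n)
        samples, md = _two_group_md(n)
        ft = FeatureTable(pd.DataFrame(
            counts, index=[f"g{i}" for i in range(n_gen)], columns=samples))
        res = nb_wald_diff_abundance(ft, md, ("grp", "A", "B"),
                                     size_factors="unit")
        assert 1.7 <= np.median(res.table["log2_fc"]) <= 2.3


# ---------------------------------------------------------------------------
# Gehan-Wilcoxon survival test
# ---------------------------------------------------------------------------

def gehan_oracle(records):
    """Direct summation of n-at-risk-weighted observed-minus-expected."""
    df = records.sort_values("time")
    times = sorted(df.loc[df["event"] == 1, "time"].unique())
    groups = sorted(df["group"].unique())
    g0 = groups[0]
    z = 0.0
    var = 0.0
    for t in times:
        at_risk = df[df["time"] >= t]
        n_tot = len(at_risk)
        d_tot = ((df["time"] == t) & (df["event"] == 1)).sum()
        n0 = (at_risk["group"] == g0).sum()
        d0 = ((df["time"] == t) & (df["event"] == 1) & (df["group"] == g0)).sum()
        w = n_tot
        z += w * (d0 - d_tot * n0 / n_tot)
        if n_tot > 1:
            var += w**2 * d_tot * (n0 / n_tot) * (1 - n0 / n_tot) * \
                (n_tot - d_tot) / (n_tot - 1)
    return z**2 / var


class TestGehanWilcoxon:
    def test_identical_groups_null(self):
        rec = pd.DataFrame({
            "time": [2, 4, 6, 8, 2, 4, 6, 8],
            "event": [1, 1, 0, 1] * 2,
            "group": ["a"] * 4 + ["b"] * 4,
        })
        out = gehan_wilcoxon_test(rec)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(60)
        for _ in range(10):
            rec = pd.DataFrame({
                "time": rng.choice(np.arange(1, 30), size=10, replace=False),
                "event": 1,
                "group": ["a"] * 5 + ["b"] * 5,
            })
            out = gehan_wilcoxon_test(rec)
            assert out["statistic"] == pytest.approx(gehan_oracle(rec), rel=1e-9)

    def test_complete_separation_is_significant(self):
        rec = pd.DataFrame({
            "time": [1, 2, 3, 4, 5, 11, 12, 13, 14, 15],
            "event": 1,
            "group": ["a"] * 5 + ["b"] * 5,
        })
        out = gehan_wilcoxon_test(rec)
        assert out["p"] < 0.01
        assert out["median_survival"]["a"] < out["median_survival"]["b"]

    def test_all_censored_errors(self):
        rec = pd.DataFrame({"time": [1, 2], "event": 0, "group": ["a", "b"]})
        with pytest.raises(ValidationError, match="censored"):
            gehan_wilcoxon_test(rec)
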