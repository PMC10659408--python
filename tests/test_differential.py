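import math

import numpy as np
import pandas as pd
import pytest

from recseq.differential import (
    DISPERSION_FLOOR,
    bh_adjust,
    classify_significant,
    estimate_dispersions,
    filter_min_counts,
    nb_wald_test,
    overlap_test,
    spearman_corr,
)


def nb_counts(rng, mu, alpha, size=None):
    if alpha <= 0:
        return rng.poisson(mu, size=size)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, np.asarray(mu) / shape, size=size)
    return rng.poisson(lam)


SAMPLES = [f"s{i}" for i in range(6)]
SF = pd.Series(1.0, index=SAMPLES)
COND = pd.Series(["A"] * 3 + ["B"] * 3, index=SAMPLES)


def _frame(arr):
    return pd.DataFrame(np.asarray(arr), columns=SAMPLES)


class TestFilterMinCounts:
    def test_strictly_greater_rule(self):
        counts = pd.DataFrame({"a": [91, 90]}, index=["t1", "t2"])
        kept = filter_min_counts(counts, 90, strict=True)
        assert list(kept) == ["t1"]

    def test_geq_rule(self):
        counts = pd.DataFrame({"a": [8, 7]}, index=["t1", "t2"])
        kept = filter_min_counts(counts, 8, strict=False)
        assert list(kept) == ["t1"]

    def test_zero_threshold_keeps_all_positive(self):
        counts = pd.DataFrame({"a": [1, 5]}, index=["t1", "t2"])
        assert len(filter_min_counts(counts, 0)) == 2

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 40, size=(50, 4)))
        kept = set(filter_min_counts(counts, 60))
        want = {i for i in counts.index if counts.loc[i].sum() > 60}
        assert kept == want


class TestBH:
    def test_hand_computed_stepup(self):
        got = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(got, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_clipped_to_one(self):
        assert bh_adjust(np.array([0.9, 0.95, 1.0])).max() == 1.0

    def test_nan_propagates_and_is_excluded(self):
        got = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(got[1])
        # remaining two adjusted with m=2
        assert np.allclose(got[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    def test_equals_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            got = bh_adjust(p)
            want = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(got, want)


class TestOverlapTest:
    def test_full_overlap_forced(self):
        universe = set(range(10))
        k, p = overlap_test(universe, universe, 10)
        assert k == 10
        assert p == pytest.approx(1.0)

    def test_disjoint_partition_p_one_for_geq_zero(self):
        a, b = set(range(5)), set(range(5, 20))
        k, p = overlap_test(a, b, 20)
        assert k == 0
        assert p == pytest.approx(1.0)

    def test_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_test(set(range(30)), set(), 20)

    def test_matches_exact_enumeration(self):
        # N=20, |A|=5, |B|=8, overlap 4: sum_{k>=4} C(8,k) C(12,5-k) / C(20,5)
        a = set(range(5))
        b = set(range(4)) | set(range(10, 14))  # |B| = 8, overlap = 4
        k, p = overlap_test(a, b, 20)
        assert k == 4
        want = sum(
            math.comb(8, j) * math.comb(12, 5 - j) for j in range(4, 6)
        ) / math.comb(20, 5)
        assert p == pytest.approx(want, rel=1e-12)


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman_corr([1, 2, 5], [10, 20, 90]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert spearman_corr([1, 2, 3, 4], [9, 7, 5, 1]) == pytest.approx(-1.0)

    def test_constant_vector_is_nan(self):
        assert np.isnan(spearman_corr([1, 1, 1], [1, 2, 3]))

    def test_tied_example_matches_rank_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        # average ranks computed by hand: x -> 1, 2.5, 2.5, 4
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 2.0, 3.0, 4.0])
        want = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y) == pytest.approx(want, rel=1e-12)


class TestDispersions:
    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(np.log(100), 0.7, 2000)
        counts = _frame(np.column_stack([nb_counts(rng, mu, 0.0) for _ in range(6)]))
        model = estimate_dispersions(counts, SF, COND)
        assert model.shrunk.median() <= 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        mu = rng.lognormal(np.log(100), 0.7, 2000)
        counts = _frame(np.column_stack([nb_counts(rng, mu, 0.1) for _ in range(6)]))
        model = estimate_dispersions(counts, SF, COND)
        assert 0.05 <= model.shrunk.median() <= 0.2

    def test_constant_counts_raw_at_floor(self):
        counts = _frame(np.full((5, 6), 50))
        model = estimate_dispersions(counts, SF, COND)
        assert (model.raw == DISPERSION_FLOOR).all()

    def test_needs_replicates(self):
        counts = _frame(np.ones((3, 6)))
        single = pd.Series([f"g{i}" for i in range(6)], index=SAMPLES)
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(counts, SF, single)

    def test_all_zero_gene_gets_trend(self):
        rng = np.random.default_rng(2)
        mu = rng.lognormal(np.log(100), 0.5, 500)
        arr = np.column_stack([nb_counts(rng, mu, 0.05) for _ in range(6)])
        arr[0] = 0
        model = estimate_dispersions(_frame(arr), SF, COND)
        assert model.shrunk.iloc[0] == pytest.approx(model.trend.iloc[0])


class TestNbWald:
    def test_identical_groups_null(self):
        arr = np.tile([[50, 60, 55]], (4, 2))  # A == B per gene
        res = nb_wald_test(_frame(arr), SF, COND, ("B", "A"), pd.Series(0.05, index=range(4)))
        assert np.allclose(res["log2FC"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)

    def test_both_zero_flagged(self):
        arr = np.zeros((2, 6))
        arr[1] = [10, 12, 9, 50, 60, 55]
        res = nb_wald_test(_frame(arr), SF, COND, ("B", "A"), pd.Series(0.05, index=range(2)))
        assert res.loc[0, "both_zero"]
        assert res.loc[0, "pvalue"] == 1.0
        assert res.loc[0, "log2FC"] == 0.0
        assert not res.loc[1, "both_zero"]

    def test_one_sided_zero_is_significant_and_finite(self):
        arr = np.array([[0, 0, 0, 80, 90, 100]])
        res = nb_wald_test(_frame(arr), SF, COND, ("B", "A"), pd.Series(0.05, index=[0]))
        assert np.isfinite(res.loc[0, "log2FC"])
        assert res.loc[0, "pvalue"] < 1e-3
        assert res.loc[0, "log2FC"] > 4

    def test_label_swap_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(5)
        mu = rng.lognormal(np.log(80), 0.5, 200)
        counts = _frame(np.column_stack([nb_counts(rng, mu, 0.05) for _ in range(6)]))
        disp = estimate_dispersions(counts, SF, COND)
        fwd = nb_wald_test(counts, SF, COND, ("B", "A"), disp)
        rev = nb_wald_test(counts, SF, COND, ("A", "B"), disp)
        assert np.allclose(fwd["log2FC"], -rev["log2FC"], atol=1e-9)
        assert np.allclose(fwd["pvalue"], rev["pvalue"], atol=1e-12)

    def test_size_factor_scaling_near_invariance(self):
        # scaling one sample's counts and its size factor by c is not an
        # exact likelihood invariance, but results must move only slightly
        rng = np.random.default_rng(6)
        mu = rng.lognormal(np.log(100), 0.5, 300)
        counts = _frame(np.column_stack([nb_counts(rng, mu, 0.05) for _ in range(6)]))
        disp = estimate_dispersions(counts, SF, COND)
        base = nb_wald_test(counts, SF, COND, ("B", "A"), disp)
        scaled = counts.copy()
        scaled["s0"] *= 3
        sf2 = SF.copy()
        sf2["s0"] = 3.0
        res = nb_wald_test(scaled, sf2, COND, ("B", "A"), disp)
        assert np.allclose(base["log2FC"], res["log2FC"], atol=0.05)
        assert np.corrcoef(base["stat"], res["stat"])[0, 1] > 0.999

    def test_null_calibration(self):
        fr = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            mu = rng.lognormal(np.log(100), 0.7, 2000)
            counts = _frame(np.column_stack([nb_counts(rng, mu, 0.05) for _ in range(6)]))
            disp = estimate_dispersions(counts, SF, COND)
            res = nb_wald_test(counts, SF, COND, ("B", "A"), disp)
            fr.append((res["pvalue"] < 0.05).mean())
        assert 0.03 <= np.mean(fr) <= 0.07

    def test_power_on_planted_fourfold(self):
        rng = np.random.default_rng(7)
        n = 2000
        eff = np.zeros(n, dtype=bool)
        eff[:200] = True
        muA = np.full(n, 100.0)
        muB = np.where(eff, 400.0, 100.0)
        arr = np.column_stack(
            [nb_counts(rng, muA, 0.05) for _ in range(3)]
            + [nb_counts(rng, muB, 0.05) for _ in range(3)]
        )
        counts = _frame(arr)
        disp = estimate_dispersions(counts, SF, COND)
        res = classify_significant(nb_wald_test(counts, SF, COND, ("B", "A"), disp))
        up = (res["class"] == "up").to_numpy()
        assert up[eff].mean() >= 0.9
        assert up[~eff].sum() <= 5


class TestClassify:
    def _res(self, padj, lfc):
        return pd.DataFrame({"padj": padj, "log2FC": lfc})

    def test_up_call(self):
        res = classify_significant(self._res([0.04], [np.log2(2.5)]))
        assert res.loc[0, "class"] == "up"

    def test_fc_gate_blocks(self):
        res = classify_significant(self._res([0.04], [np.log2(1.5)]))
        assert res.loc[0, "class"] == "ns"

    def test_fdr_gate_blocks(self):
        res = classify_significant(self._res([0.06], [np.log2(3.0)]))
        assert res.loc[0, "class"] == "ns"

    def test_down_call(self):
        res = classify_significant(self._res([0.01], [np.log2(0.4)]))
        assert res.loc[0, "class"] == "down"
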