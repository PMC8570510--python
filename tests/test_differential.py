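"""Normalisation and NB Wald differential testing."""

import numpy as np
import pandas as pd
import pytest

from ctxatac.differential import (
    bh_fdr,
    call_differential,
    classify_context,
    expressed_features,
    gc_quantile_offsets,
    nb_wald_test,
    select_background,
    size_factors,
)


def nb_counts(rng, mean, alpha=0.05):
    lam = rng.gamma(1 / alpha, alpha * np.asarray(mean, float))
    return rng.poisson(lam)


class TestSizeFactors:
    def test_doubled_sample(self, rng):
        a = rng.poisson(100, size=200)
        counts = pd.DataFrame({"s1": a + 1, "s2": 2 * (a + 1)})
        sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0, rel=1e-9)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_single_sample(self):
        counts = pd.DataFrame({"s1": [5, 10, 2]})
        assert size_factors(counts)["s1"] == 1.0

    def test_random_vs_median_of_ratios_oracle(self, rng):
        counts = pd.DataFrame(
            nb_counts(rng, np.outer(rng.gamma(3, 40, 300), rng.uniform(0.5, 2, 4))),
            columns=list("abcd"),
        )
        sf = size_factors(counts)
        y = counts.to_numpy(float)
        pos = (y > 0).all(axis=1)
        ratios = np.log(y[pos]) - np.log(y[pos]).mean(axis=1, keepdims=True)
        expect = np.median(ratios, axis=0)
        expect = np.exp(expect - expect.mean())
        assert sf.to_numpy() == pytest.approx(expect)

    def test_no_all_positive_feature_errors(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [4, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)


class TestGCQuantileOffsets:
    def test_single_bin_factors_are_one(self, rng):
        counts = pd.DataFrame({"s1": rng.poisson(50, 40), "s2": rng.poisson(80, 40)})
        gc = pd.Series(rng.uniform(0.3, 0.7, 40), index=counts.index)
        f = gc_quantile_offsets(counts, gc, n_bins=1, rescale=False)
        assert np.allclose(f.to_numpy(), 1.0)

    def test_two_bins_equalised(self, rng):
        # bin2 counts = 3x bin1 counts rank-for-rank; quantile mapping should
        # equalise the bin means of normalised counts within the sample
        base = np.sort(rng.poisson(100, 50)).astype(float)
        counts = pd.DataFrame({"s1": np.concatenate([base, 3 * base])})
        gc = pd.Series(np.concatenate([np.full(50, 0.3), np.full(50, 0.7)]))
        f = gc_quantile_offsets(counts, gc, n_bins=2, rescale=False)
        normalized = counts["s1"] / f["s1"]
        m1, m2 = normalized[:50].mean(), normalized[50:].mean()
        assert m2 / m1 == pytest.approx(1.0, rel=0.02)

    def test_rank_order_preserved_within_bin(self, rng):
        counts = pd.DataFrame({"s1": rng.poisson(60, 100)})
        gc = pd.Series(rng.uniform(0.2, 0.8, 100))
        f = gc_quantile_offsets(counts, gc, n_bins=4, rescale=False)
        normalized = counts["s1"] / f["s1"]
        order = np.argsort(gc.to_numpy(), kind="stable")
        bins = np.minimum((np.arange(100) * 4) // 100, 3)
        bin_of = np.empty(100, dtype=int)
        bin_of[order] = bins
        for b in range(4):
            raw = counts["s1"][bin_of == b].to_numpy()
            nrm = normalized[bin_of == b].to_numpy()
            # monotone map: equal ranks
            assert (np.argsort(np.argsort(raw)) == np.argsort(np.argsort(nrm))).all()

    def test_bin_reduction_warning(self, rng):
        counts = pd.DataFrame({"s1": [5, 6, 7]})
        gc = pd.Series([0.3, 0.5, 0.7])
        with pytest.warns(UserWarning, match="bins"):
            gc_quantile_offsets(counts, gc, n_bins=10)

    def test_missing_gc_errors(self):
        counts = pd.DataFrame({"s1": [5, 6]}, index=["a", "b"])
        with pytest.raises(ValueError, match="GC"):
            gc_quantile_offsets(counts, pd.Series({"a": 0.5}))

    def test_removes_planted_gc_bias(self, rng):
        # sample s1 carries a strong GC-linked multiplicative bias, s2 none;
        # after normalisation the GC association of the s1/s2 ratio shrinks
        gc = pd.Series(rng.uniform(0.2, 0.8, 600))
        base = rng.gamma(3, 50, 600)
        bias = np.exp(2.5 * (gc - 0.5))
        counts = pd.DataFrame(
            {"s1": rng.poisson(base * bias) + 1, "s2": rng.poisson(base) + 1}
        )
        f = gc_quantile_offsets(counts, gc)
        before = np.corrcoef(gc, np.log(counts["s1"] / counts["s2"]))[0, 1]
        ratio = np.log(counts["s1"] / f["s1"]) - np.log(counts["s2"] / f["s2"])
        after = np.corrcoef(gc, ratio)[0, 1]
        assert abs(before) > 0.5
        assert abs(after) < 0.15


class TestNBWald:
    def _frame(self, y):
        return pd.DataFrame(y, columns=[f"s{i}" for i in range(y.shape[1])])

    def _groups(self, n):
        return {f"s{i}": ("A" if i < n // 2 else "B") for i in range(n)}

    def test_poisson_limit_matches_lr_oracle(self, rng):
        # large counts, no overdispersion: NB Wald ~ Poisson GLM LR test
        import statsmodels.api as sm

        y = rng.poisson(
            np.outer(rng.gamma(5, 100, 40), np.r_[np.ones(6), 1.3 * np.ones(6)])
        )
        counts = self._frame(y)
        res = nb_wald_test(counts, self._groups(12), ("B", "A"))
        group = np.r_[np.zeros(6), np.ones(6)]
        X = sm.add_constant(group)
        agree = 0
        for i in range(40):
            full = sm.GLM(y[i], X, family=sm.families.Poisson()).fit()
            null = sm.GLM(y[i], np.ones((12, 1)), family=sm.families.Poisson()).fit()
            from scipy.stats import chi2

            lr_p = chi2.sf(2 * (full.llf - null.llf), df=1)
            if lr_p < 1e-12 or res["p"].iloc[i] < 1e-12:
                agree += 1  # both overwhelming
                continue
            if abs(np.log10(res["p"].iloc[i]) - np.log10(lr_p)) < np.log10(1.35):
                agree += 1
        assert agree >= 36  # within ~10 % on the log-p scale for nearly all

    def test_planted_strong_effect(self, rng):
        mean = np.full((100, 10), 500.0)
        mean[:5, 5:] *= 2.0**3  # planted LFC = 3 on five features
        y = nb_counts(rng, mean)
        res = nb_wald_test(self._frame(y), self._groups(10), ("B", "A"))
        assert (res["q"].iloc[:5] < 1e-4).all()
        assert res["lfc"].iloc[:5].mean() == pytest.approx(3.0, abs=0.3)

    def test_label_swap_negates_lfc(self, rng):
        y = nb_counts(rng, np.full((50, 10), 120.0))
        counts = self._frame(y)
        a = nb_wald_test(counts, self._groups(10), ("B", "A"))
        b = nb_wald_test(counts, self._groups(10), ("A", "B"))
        assert a["lfc"].to_numpy() == pytest.approx(-b["lfc"].to_numpy(), abs=1e-6)
        assert a["p"].to_numpy() == pytest.approx(b["p"].to_numpy(), rel=1e-6)

    def test_all_zero_feature_gets_na(self, rng):
        y = nb_counts(rng, np.full((10, 10), 50.0))
        y[3] = 0
        res = nb_wald_test(self._frame(y), self._groups(10), ("B", "A"))
        assert np.isnan(res["p"].iloc[3]) and np.isnan(res["q"].iloc[3])
        assert res["p"].drop(res.index[3]).notna().all()

    def test_requires_two_per_group(self, rng):
        y = nb_counts(rng, np.full((5, 3), 50.0))
        counts = self._frame(y)
        with pytest.raises(ValueError):
            nb_wald_test(counts, {"s0": "A", "s1": "B", "s2": "B"}, ("B", "A"))

    def test_sample_scaling_absorbed_by_offsets(self, rng):
        y = nb_counts(rng, np.full((80, 10), 200.0))
        counts = self._frame(y)
        doubled = counts.copy()
        doubled["s0"] = doubled["s0"] * 2
        sf = size_factors(doubled)
        offsets = pd.DataFrame(
            np.tile(sf.to_numpy(), (80, 1)), index=counts.index, columns=counts.columns
        )
        res = nb_wald_test(doubled, self._groups(10), ("B", "A"), offsets)
        assert (res["q"] > 0.05).mean() > 0.95


class TestBH:
    def test_hand_computed(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.37]) == pytest.approx([0.37])

    def test_random_vs_step_up_oracle(self, rng):
        for _ in range(30):
            p = rng.uniform(size=rng.integers(1, 40))
            got = bh_fdr(p)
            n = len(p)
            order = np.argsort(p)
            ranked = p[order] * n / np.arange(1, n + 1)
            expect_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
            expect = np.empty(n)
            expect[order] = np.minimum(expect_sorted, 1.0)
            assert got == pytest.approx(expect)
            assert (got >= p - 1e-12).all()

    def test_na_excluded_from_denominator(self):
        q = bh_fdr(pd.Series([0.01, np.nan, 0.04]))
        assert np.isnan(q.iloc[1])
        assert q.iloc[0] == pytest.approx(0.02)  # n = 2, not 3


class TestCallsAndClasses:
    def _res(self, rows):
        df = pd.DataFrame(rows, columns=["lfc", "q"])
        df["se"] = 0.1
        df["p"] = df["q"] / 2
        return df

    @pytest.mark.parametrize(
        "lfc,q,expect",
        [
            (1.2, 0.04, True),
            (1.0, 0.04, False),  # strict |lfc| > 1
            (1.2, 0.05, False),  # strict q < 0.05
            (-1.5, 0.01, True),
        ],
    )
    def test_call_boundaries(self, lfc, q, expect):
        called = call_differential(self._res([(lfc, q)]))
        assert bool(called["significant"].iloc[0]) is expect

    def _three(self, patterns):
        # patterns: per comparison, (lfc, q) per feature
        return {
            label: call_differential(self._res(rows))
            for label, rows in patterns.items()
        }

    def test_classification_patterns(self):
        res = self._three(
            {
                #                 f0: pre,     f1: adipo,   f2: mature,  f3: other,   f4: none
                "D4_vs_D0": [(-2, 0.01), (2, 0.01), (0.2, 0.9), (-2, 0.01), (0.1, 0.9)],
                "D14_vs_D0": [(-2, 0.01), (2, 0.01), (2, 0.01), (0.2, 0.9), (0.1, 0.9)],
                "D14_vs_D4": [(0.1, 0.9), (0.1, 0.9), (2, 0.01), (0.3, 0.9), (0.1, 0.9)],
            }
        )
        cls = classify_context(res)
        assert list(cls) == [
            "preadipocyte_dependent",
            "adipocyte_dependent",
            "mature_adipocyte_specific",
            "other_context_dependent",
            "non_differential",
        ]

    def test_missing_comparison_errors(self):
        res = self._three({"D4_vs_D0": [(0, 1)], "D14_vs_D0": [(0, 1)]})
        with pytest.raises(ValueError, match="D14_vs_D4"):
            classify_context(res)

    def test_background_selection(self):
        res = self._three(
            {
                "D4_vs_D0": [(0.5, 0.6), (0.5, 0.4), (1.2, 0.6)],
                "D14_vs_D0": [(0.3, 0.7), (0.3, 0.7), (0.2, 0.9)],
                "D14_vs_D4": [(-0.2, 0.9), (0.1, 0.9), (0.1, 0.9)],
            }
        )
        # f0 background; f1 fails q > 0.5 in one comparison; f2 fails |lfc| < 1
        assert list(select_background(res)) == [0]


class TestExpressedFeatures:
    def test_boundary(self):
        counts = pd.DataFrame({"s1": [2, 1], "s2": [2, 1]}, index=["g1", "g2"])
        sf = pd.Series({"s1": 2.0, "s2": 2.0})
        kept = expressed_features(counts, sf, min_median=1.0)
        assert list(kept) == ["g1"]  # g1 median normalised exactly 1.0, g2 is 0.5

    def test_fraction_below_one_dropped(self):
        counts = pd.DataFrame({"s1": [99], "s2": [99]}, index=["g"])
        sf = pd.Series({"s1": 100.0, "s2": 100.0})
        assert len(expressed_features(counts, sf)) == 0
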