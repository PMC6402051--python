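"""Agreement statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pc4dflow import agreement as ag


# ---------------------------------------------------------------- oracles
def _rank_oracle(x):
    """Midranks computed by direct definition."""
    x = np.asarray(x, dtype=float)
    out = np.empty(x.size)
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        out[i] = less + (equal + 1) / 2.0
    return out


def _wilcoxon_oracle(a, b):
    """Exact two-sided signed-rank p by explicit itertools enumeration."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = _rank_oracle(np.abs(d))
    total = ranks.sum()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if min(w_plus, total - w_plus) <= w_obs + 1e-9:
            count += 1
    return w_obs, count / 2.0**n


class TestBlandAltman:
    def test_identical_methods(self):
        res = ag.bland_altman([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.bias == 0.0 and res.sd == 0.0

    def test_worked_example(self):
        """d = (-2, 2, -3): bias -1.0, sample SD sqrt(7)."""
        res = ag.bland_altman([10.0, 20.0, 30.0], [12.0, 18.0, 33.0])
        assert res.bias == pytest.approx(-1.0, abs=1e-12)
        assert res.sd == pytest.approx(np.sqrt(7.0), abs=1e-12)
        assert res.loa_low == pytest.approx(-1.0 - 1.96 * np.sqrt(7.0))
        assert res.loa_high == pytest.approx(-1.0 + 1.96 * np.sqrt(7.0))

    @settings(derandomize=True, max_examples=40)
    @given(
        vals=st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=2,
            max_size=12,
        ),
        c=st.floats(-50, 50, allow_nan=False),
    )
    def test_translation_shifts_bias_only(self, vals, c):
        a = np.array([v[0] for v in vals])
        b = np.array([v[1] for v in vals])
        r0 = ag.bland_altman(a, b)
        r1 = ag.bland_altman(a + c, b)
        assert r1.bias == pytest.approx(r0.bias + c, abs=1e-8)
        assert r1.sd == pytest.approx(r0.sd, abs=1e-8)

    def test_matches_formula_oracle_on_random_input(self, rng):
        a, b = rng.normal(0, 10, 30), rng.normal(0, 10, 30)
        res = ag.bland_altman(a, b)
        d = a - b
        assert res.bias == pytest.approx(d.mean(), abs=1e-10)
        assert res.sd == pytest.approx(
            np.sqrt(((d - d.mean()) ** 2).sum() / (len(d) - 1)), abs=1e-10
        )

    def test_insufficient_pairs(self):
        with pytest.raises(ValueError):
            ag.bland_altman([1.0], [2.0])


class TestPearsonRegression:
    def test_exact_linear_relation(self):
        b = np.array([1.0, 2.0, 3.0, 4.0])
        r, slope, intercept = ag.pearson_regression(2 * b + 1, b)
        assert (r, slope, intercept) == (
            pytest.approx(1.0), pytest.approx(2.0), pytest.approx(1.0))

    def test_zero_sample_covariance(self):
        b = np.array([-1.0, 0.0, 1.0, 0.0])
        a = np.array([0.0, 1.0, 0.0, -1.0])  # cov(a, b) = 0 by construction
        r, slope, _ = ag.pearson_regression(a, b)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        a, b = rng.normal(0, 5, 50), rng.normal(0, 5, 50)
        r, slope, intercept = ag.pearson_regression(a, b)
        X = np.column_stack([np.ones(50), b])
        beta = np.linalg.inv(X.T @ X) @ X.T @ a
        assert intercept == pytest.approx(beta[0], abs=1e-10)
        assert slope == pytest.approx(beta[1], abs=1e-10)
        r_oracle = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert r == pytest.approx(r_oracle, abs=1e-10)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            ag.pearson_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestWilcoxon:
    def test_three_positive_differences(self):
        """d = (+1, +2, +3): W = 0; 2 of the 8 sign patterns reach
        min(W+, W-) = 0, so the exact two-sided p is 0.25."""
        w, p = ag.wilcoxon_signed_rank([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert w == 0.0
        assert p == pytest.approx(0.25, abs=1e-12)

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning):
            _, p = ag.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        pairs=st.lists(
            st.tuples(st.integers(-5, 5), st.integers(-5, 5)),
            min_size=1,
            max_size=9,
        )
    )
    def test_exact_p_matches_enumeration_oracle(self, pairs):
        a = np.array([p[0] for p in pairs], dtype=float)
        b = np.array([p[1] for p in pairs], dtype=float)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p = ag.wilcoxon_signed_rank(a, b)
            w_o, p_o = _wilcoxon_oracle(a, b)
        assert w == pytest.approx(w_o, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-12)
        assert 0.0 < p <= 1.0

    def test_symmetric_under_swapping_methods(self, rng):
        a, b = rng.normal(0, 3, 10), rng.normal(0, 3, 10)
        w1, p1 = ag.wilcoxon_signed_rank(a, b)
        w2, p2 = ag.wilcoxon_signed_rank(b, a)
        assert w1 == w2 and p1 == p2

    def test_matches_scipy_exact_when_tie_free(self, rng):
        from scipy import stats

        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 12)
        _, p = ag.wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, mode="exact", alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_normal_approximation(self, rng):
        from scipy import stats

        a = rng.normal(0.3, 1, 60)
        b = rng.normal(0.0, 1, 60)
        _, p = ag.wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, mode="approx", alternative="two-sided",
                             correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestComparisonTable:
    def _cohort(self, rng, offset=-5.0, noise=0.0, n=8):
        rows = []
        for s in range(n):
            ref = 60.0 + 3.0 * s
            rows.append(dict(subject=s, method="2D", metric="aorta", value=ref))
            rows.append(
                dict(subject=s, method="4D", metric="aorta",
                     value=ref + offset + rng.normal(0, noise) if noise else ref + offset)
            )
        return pd.DataFrame(rows)

    def test_identical_sets_give_zero_bias(self, rng):
        df = self._cohort(rng, offset=0.0)
        table = ag.build_comparison_table(
            df, [ag.Comparison("4Dvs2D", {"method": "4D"}, {"method": "2D"})]
        )
        assert np.allclose(table["bias"], 0.0)

    def test_constructed_offset_recovered(self, rng):
        df = self._cohort(rng, offset=-5.0)
        table = ag.build_comparison_table(
            df, [ag.Comparison("4Dvs2D", {"method": "4D"}, {"method": "2D"})]
        )
        assert np.allclose(table["bias"], -5.0)
        assert np.allclose(table["sd"], 0.0)
        assert (table["n"] == 8).all()

    def test_sampling_distribution_bound(self, rng):
        """A cohort with prescribed differences N(-4, 10^2), n = 30,
        recovers the prescribed bias within 3 standard errors."""
        df = self._cohort(rng, offset=0.0, n=30)
        diffs = rng.normal(-4.0, 10.0, 30)
        df.loc[df["method"] == "4D", "value"] = (
            df.loc[df["method"] == "2D", "value"].to_numpy() + diffs
        )
        table = ag.build_comparison_table(
            df, [ag.Comparison("4Dvs2D", {"method": "4D"}, {"method": "2D"})]
        )
        assert abs(table["bias"].iloc[0] - (-4.0)) < 3.0 * 10.0 / np.sqrt(30)

    def test_invariant_to_row_order(self, rng):
        df = self._cohort(rng, offset=-2.0, noise=1.0)
        design = [ag.Comparison("4Dvs2D", {"method": "4D"}, {"method": "2D"})]
        t1 = ag.build_comparison_table(df, design)
        t2 = ag.build_comparison_table(df.sample(frac=1.0, random_state=7), design)
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_pairs_dropped_and_counted(self, rng):
        df = self._cohort(rng, offset=-5.0)
        df = df.drop(df[(df["subject"] == 0) & (df["method"] == "4D")].index)
        table = ag.build_comparison_table(
            df, [ag.Comparison("4Dvs2D", {"method": "4D"}, {"method": "2D"})]
        )
        assert table["n"].iloc[0] == 7
        assert table["n_dropped"].iloc[0] == 1

    def test_no_complete_pairs_is_error(self):
        df = pd.DataFrame(
            [dict(subject=0, method="4D", metric="aorta", value=1.0),
             dict(subject=1, method="2D", metric="aorta", value=2.0)]
        )
        with pytest.raises(ValueError):
            ag.build_comparison_table(
                df, [ag.Comparison("c", {"method": "4D"}, {"method": "2D"})]
            )
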