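import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import comb

from ewaskit import (
    ContingencyTable,
    bh_fdr,
    chi_square_test,
    inflation_lambda,
    summarize_cohort,
    trend_test,
    wallenius_test,
)

# printed cohort tables: rows = covariate levels, columns = TD / nonTD / ASD
SEX_TABLE = [[26, 30, 7], [21, 27, 22]]
BATCH_TABLE = [[31, 37, 19], [16, 20, 10]]
SITE_TABLE = [[20, 8, 6], [4, 20, 9], [11, 21, 8], [12, 8, 6]]


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,printed_p,decimals",
        [
            (SEX_TABLE, 0.017, 3),
            (BATCH_TABLE, 0.99, 2),
            (SITE_TABLE, 0.003, 3),
        ],
    )
    def test_cohort_tables_reproduce_printed_pvalues(self, table, printed_p, decimals):
        _, _, p, _ = chi_square_test(np.array(table))
        assert round(p, decimals) == printed_p

    def test_proportional_table_gives_zero_statistic(self):
        chi2, df, p, _ = chi_square_test(np.array([[10, 20], [5, 10]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_enrichment_table_matches_closed_formula(self):
        a, b, c, d = 488, 351, 7742, 10432
        chi2, df, p, exp = chi_square_test(np.array([[a, b], [c, d]]))
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(closed, rel=1e-12)
        assert chi2 == pytest.approx(79.146, abs=0.001)

    @given(
        st.lists(st.integers(min_value=1, max_value=200), min_size=4, max_size=4)
    )
    @settings(max_examples=50, deadline=None)
    def test_2x2_always_matches_closed_formula(self, cells):
        a, b, c, d = cells
        chi2, _, _, exp = chi_square_test(np.array([[a, b], [c, d]]))
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(closed, rel=1e-9)
        np.testing.assert_allclose(exp.sum(axis=0), np.array([[a, b], [c, d]]).sum(axis=0), rtol=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_test(np.array([[0, 0], [1, 2]]))

    def test_contingency_table_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, -2], [3, 4]]))
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, 2]]))


class TestTrendTest:
    def test_extreme_monotone_trend_highly_significant(self):
        scores = np.repeat([0, 1, 2], 300)
        x = np.concatenate([
            (np.arange(300) < 30).astype(float),
            (np.arange(300) < 150).astype(float),
            (np.arange(300) < 270).astype(float),
        ])
        assert trend_test(scores, x) < 1e-6

    def test_equal_proportions_give_p_one(self):
        scores = np.repeat([0, 1, 2], 10)
        x = np.concatenate([[0, 1] * 5] * 3).astype(float)
        assert trend_test(scores, x) == pytest.approx(1.0, abs=1e-9)

    def test_constant_variable_gives_p_one(self):
        assert trend_test([0, 1, 2, 0, 1, 2], [1, 1, 1, 1, 1, 1]) == 1.0

    def test_null_calibration_uniform(self):
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(1000):
            scores = rng.integers(0, 3, 150)
            x = (rng.random(150) < 0.4).astype(float)
            ps.append(trend_test(scores, x))
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_hand_computed_stepup_values(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04]
        )

    def test_degenerate_cases(self):
        np.testing.assert_allclose(bh_fdr(np.array([1.0, 1.0])), [1.0, 1.0])
        np.testing.assert_allclose(bh_fdr(np.array([0.01])), [0.01])

    def test_nan_propagates_without_affecting_others(self):
        q = bh_fdr(np.array([0.01, np.nan, 0.02, 0.04]))
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2, 3]], [0.03, 0.03, 0.04])

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=500) ** 2
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_ref, rtol=1e-12)

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_input_order(self, plist):
        p = np.array(plist)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        q_direct = bh_fdr(p)
        q_perm = np.empty_like(q_direct)
        q_perm[perm] = bh_fdr(p[perm])
        np.testing.assert_allclose(q_direct, q_perm, rtol=1e-12)
        assert (q_direct >= p - 1e-12).all()


class TestInflationLambda:
    def test_all_half_pvalues_give_unity(self):
        assert inflation_lambda(np.full(200, 0.5)) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_null_near_unity(self):
        rng = np.random.default_rng(11)
        lams = [inflation_lambda(rng.uniform(size=10000)) for _ in range(5)]
        assert all(0.9 < lam < 1.1 for lam in lams)
        assert 0.97 < np.mean(lams) < 1.03

    def test_planted_inflation_recovered(self):
        rng = np.random.default_rng(12)
        chi2 = 1.2 * rng.chisquare(1, 10000)
        p = sps.chi2.sf(chi2, 1)
        assert inflation_lambda(p) == pytest.approx(1.2, abs=0.05)


def brute_force_hypergeom_upper(N, K, n, k):
    """Enumerate all C(N, n) draws; fraction with >= k category members."""
    hits = tot = 0
    for sel in itertools.combinations(range(N), n):
        tot += 1
        hits += sum(1 for i in sel if i < K) >= k
    return hits / tot


class TestWallenius:
    def test_central_reduction_equals_fisher(self):
        p_w = wallenius_test(4, 4, 5, 10, odds=1.0)
        p_h = float(sps.hypergeom.sf(3, 10, 4, 5))
        assert p_w == pytest.approx(p_h, rel=1e-9)

    def test_matches_exhaustive_enumeration_252_draws(self):
        assert wallenius_test(4, 4, 5, 10, odds=1.0) == pytest.approx(
            brute_force_hypergeom_upper(10, 4, 5, 4), rel=1e-9
        )

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 4, 5), (12, 5, 6), (11, 2, 7)])
    def test_small_universe_enumeration(self, N, K, n):
        for k in range(0, min(K, n) + 1):
            assert wallenius_test(k, K, n, N, odds=1.0) == pytest.approx(
                brute_force_hypergeom_upper(N, K, n, k), rel=1e-9, abs=1e-12
            )

    def test_monotone_nondecreasing_in_odds(self):
        # higher sampling odds for category genes make a large overlap less
        # surprising: the upper-tail p grows with odds (towards 1), and
        # vanishes as the odds go to zero
        ps = [wallenius_test(4, 6, 8, 20, odds=o) for o in (0.05, 0.5, 1, 2, 5, 20)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))
        assert ps[0] < 0.01
        assert ps[-1] > 0.9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wallenius_test(5, 4, 5, 10)
        with pytest.raises(ValueError):
            wallenius_test(2, 4, 5, 10, odds=0.0)


class TestSummarizeCohort:
    @pytest.mark.parametrize(
        "table,levels,cov,printed_p,decimals",
        [
            (BATCH_TABLE, ["1", "2"], "batch", 0.99, 2),
            (SITE_TABLE, ["Drexel", "JHU", "Kaiser", "UCD"], "site", 0.003, 3),
        ],
    )
    def test_printed_cohort_pvalues(self, table, levels, cov, printed_p, decimals):
        outcomes, values = [], []
        for lev, row in zip(levels, table):
            for grp, count in zip(["TD", "nonTD", "ASD"], row):
                outcomes.extend([grp] * count)
                values.extend([lev] * count)
        sheet = pd.DataFrame(
            {"outcome": outcomes, cov: values},
            index=[f"S{i}" for i in range(len(outcomes))],
        )
        out = summarize_cohort(sheet, covariates=[cov])
        p = out["p"].dropna().iloc[0]
        assert round(p, decimals) == printed_p

    def test_continuous_covariate_null_uniform(self):
        rng = np.random.default_rng(23)
        ps = []
        for _ in range(300):
            sheet = pd.DataFrame(
                {
                    "outcome": rng.choice(["TD", "nonTD", "ASD"], 150),
                    "age": rng.normal(33, 5, 150),
                },
                index=[f"S{i}" for i in range(150)],
            )
            out = summarize_cohort(sheet, covariates=["age"])
            ps.append(out["p"].dropna().iloc[0])
        assert sps.kstest(ps, "uniform").pvalue > 0.01
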