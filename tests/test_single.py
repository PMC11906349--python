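"""Rank-inverse normalisation, log-space P, marginal scan and CoJo
selection, each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cispqtl import single


class TestRankInverseNormalize:
    def test_middle_value_maps_to_zero(self):
        x = np.array([3.0, 1.0, 2.0, 5.0, 4.0])
        out = single.rank_inverse_normalize(x)
        assert out[np.argsort(x)[2]] == pytest.approx(0.0, abs=1e-12)

    def test_output_symmetric(self, rng):
        x = rng.normal(size=101)
        out = np.sort(single.rank_inverse_normalize(x))
        np.testing.assert_allclose(out, -out[::-1], atol=1e-12)

    def test_blom_closed_form_n5(self):
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        out = single.rank_inverse_normalize(x)
        expected = stats.norm.ppf((np.arange(1, 6) - 0.375) / 5.25)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_ties_get_average_rank(self):
        out = single.rank_inverse_normalize(np.array([1.0, 1.0, 2.0, 3.0]))
        assert out[0] == out[1]

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="identical"):
            single.rank_inverse_normalize(np.full(10, 3.0))

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            single.rank_inverse_normalize(np.array([1.0, 2.0]))


class TestLog10P:
    def test_beta_zero_gives_log10p_zero(self):
        assert single.log10p_from_t(0.0, 1.0, 100) == pytest.approx(0.0)

    def test_matches_mpmath_oracle(self):
        # independent high-precision oracle for the log-space t tail
        import mpmath

        mpmath.mp.dps = 50

        def oracle(t, df):
            x = mpmath.mpf(df) / (df + mpmath.mpf(t) ** 2)
            sf = mpmath.betainc(df / mpmath.mpf(2), mpmath.mpf("0.5"),
                                0, x, regularized=True) / 2
            return float(mpmath.log10(2 * sf))

        for t, n in [(1, 100), (10, 100), (50, 1_000), (300, 50_000)]:
            mine = single.log10p_from_t(float(t), 1.0, n)
            assert mine == pytest.approx(oracle(t, n - 2), rel=1e-6)

    def test_finite_and_monotone_at_extreme_t(self):
        vals = [single.log10p_from_t(t, 1.0, 50_000)
                for t in (10, 50, 100, 300)]
        assert all(np.isfinite(v) for v in vals)
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_se_nonpositive_errors(self):
        with pytest.raises(ValueError, match="se"):
            single.log10p_from_t(1.0, 0.0, 100)

    def test_df_mode_switch(self):
        a = single.log10p_from_t(3.0, 1.0, 100, k_covariates=50,
                                 df_mode="n_minus_2")
        b = single.log10p_from_t(3.0, 1.0, 100, k_covariates=50,
                                 df_mode="n_minus_k_minus_2")
        assert a != b


def _toy_data(rng, n=50, m=8, k=3):
    G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    X = rng.normal(size=(n, k))
    beta = np.zeros(m)
    beta[0] = 0.8
    y = G @ beta + X @ np.array([0.5, -0.3, 0.2]) + rng.normal(size=n)
    cov = pd.DataFrame(X, columns=["c1", "c2", "c3"])
    return G, y, cov


class TestSingleVariantAssoc:
    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        G, y, cov = _toy_data(rng)
        res = single.single_variant_assoc(G, y, cov, min_mac=0)
        for _, row in res.iterrows():
            j = int(row["idx"])
            X = sm.add_constant(np.column_stack([G[:, j], cov.to_numpy()]))
            fit = sm.OLS(y, X).fit()
            assert row["beta"] == pytest.approx(fit.params[1], abs=1e-10)
            assert row["se"] == pytest.approx(fit.bse[1], abs=1e-10)
            assert row["p"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_mac_below_threshold_absent(self, rng):
        n = 200
        G = np.zeros((n, 2))
        G[:4, 0] = 1  # MAC 4
        G[:5, 1] = 1  # MAC 5
        y = rng.normal(size=n)
        res = single.single_variant_assoc(G, y, None, min_mac=5)
        assert res["idx"].tolist() == [1]

    def test_null_pvalues_uniform(self):
        # pooled over 10 seeds; KS against Uniform(0,1)
        pvals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            G = rng.binomial(2, 0.2, size=(300, 150)).astype(float)
            y = rng.normal(size=300)
            res = single.single_variant_assoc(G, y, None, min_mac=5)
            pvals.append(res["p"].to_numpy())
        ks = stats.kstest(np.concatenate(pvals), "uniform")
        assert ks.pvalue > 0.01

    def test_collinear_covariates_named(self, rng):
        G, y, cov = _toy_data(rng)
        cov["dup"] = cov["c1"]
        with pytest.raises(ValueError, match="dup|c1"):
            single.single_variant_assoc(G, y, cov)


class TestLdR2:
    def test_self_correlation_is_one(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        assert single.ld_r2(g, g) == pytest.approx(1.0)

    def test_hand_computed_six_samples(self):
        a = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        b = np.array([0, 1, 1, 0, 0, 2], dtype=float)
        r = np.corrcoef(a, b)[0, 1]
        assert single.ld_r2(a, b) == pytest.approx(r * r, abs=1e-12)

    def test_independent_variants_low_r2(self):
        rng = np.random.default_rng(0)
        G = rng.binomial(2, 0.3, size=(10_000, 40)).astype(float)
        r2 = [single.ld_r2(G[:, i], G[:, j])
              for i in range(40) for j in range(i + 1, 40)]
        assert np.mean(np.array(r2) < 0.01) >= 0.99

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            single.ld_r2(np.zeros(10), np.ones(10))

    def test_missing_pairwise_dropped(self):
        a = np.array([0, 1, 2, np.nan, 1], dtype=float)
        b = np.array([0, 1, 2, 2.0, 1], dtype=float)
        assert single.ld_r2(a, b) == pytest.approx(1.0)


class TestCojoSelect:
    def test_single_causal_selected_joint_equals_marginal(self):
        rng = np.random.default_rng(3)
        n = 1_000
        G = rng.binomial(2, 0.3, size=(n, 30)).astype(float)
        y = 0.6 * G[:, 7] + rng.normal(size=n)
        sig = single.cojo_select(G, y, None, p_threshold=1e-8)
        assert sig.selected_idx.tolist() == [7]
        row = sig.table.iloc[0]
        assert row["beta_joint"] == pytest.approx(row["beta_marginal"],
                                                  abs=1e-8)

    def test_two_independent_causals_match_normal_equations(self):
        rng = np.random.default_rng(4)
        n = 2_000
        G = rng.binomial(2, 0.25, size=(n, 40)).astype(float)
        y = 0.5 * G[:, 3] - 0.45 * G[:, 30] + rng.normal(size=n)
        sig = single.cojo_select(G, y, None, p_threshold=1e-8)
        assert set(sig.selected_idx) == {3, 30}
        # normal-equations oracle on [1, g3, g30]
        X = np.column_stack([np.ones(n), G[:, 3], G[:, 30]])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        tbl = sig.table.set_index("idx")
        assert tbl.loc[3, "beta_joint"] == pytest.approx(coef[1], abs=1e-8)
        assert tbl.loc[30, "beta_joint"] == pytest.approx(coef[2], abs=1e-8)

    def test_duplicated_variant_selects_exactly_one(self):
        rng = np.random.default_rng(5)
        n = 1_500
        g = rng.binomial(2, 0.3, size=n).astype(float)
        G = np.column_stack([g, g, rng.binomial(2, 0.3, size=n)])
        y = 0.7 * g + rng.normal(size=n)
        sig = single.cojo_select(G, y, None, p_threshold=1e-8)
        assert len(sig) == 1
        assert sig.selected_idx[0] in (0, 1)

    def test_nothing_significant_returns_empty(self, rng):
        G = rng.binomial(2, 0.3, size=(200, 20)).astype(float)
        y = rng.normal(size=200)
        sig = single.cojo_select(G, y, None, p_threshold=1e-10)
        assert len(sig) == 0
        assert sig.max_abs_beta_discrepancy == 0.0

    def test_joint_model_equals_direct_regression(self):
        """Oracle equivalence: selected-set joint estimates equal the
        all-in-one multiple regression (LD panel = discovery sample)."""
        rng = np.random.default_rng(6)
        n = 1_500
        base = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        # correlated block: noisy copies of base columns
        noise = rng.binomial(2, 0.05, size=(n, 5)).astype(float)
        G = np.column_stack([base, np.clip(base + noise, 0, 2)])
        y = 0.5 * G[:, 0] - 0.4 * G[:, 2] + rng.normal(size=n)
        sig = single.cojo_select(G, y, None, p_threshold=1e-6)
        assert len(sig) >= 1
        X = np.column_stack([np.ones(n), G[:, sig.selected_idx]])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(sig.table["beta_joint"].to_numpy(),
                                   coef[1:], atol=1e-8)

    def test_all_members_below_threshold(self):
        rng = np.random.default_rng(8)
        n = 2_000
        G = rng.binomial(2, 0.3, size=(n, 50)).astype(float)
        y = 0.5 * G[:, 10] + 0.4 * G[:, 20] + rng.normal(size=n)
        sig = single.cojo_select(G, y, None, p_threshold=1e-8)
        assert (sig.table["p_joint"] < 1e-8).all()


class TestVarianceExplained:
    def test_empty_signal_set_zero(self, rng):
        G = rng.binomial(2, 0.3, size=(100, 5)).astype(float)
        y = rng.normal(size=100)
        sig = single.cojo_select(G, y, None, p_threshold=1e-12)
        assert single.variance_explained(sig, G, y, None) == 0.0

    def test_near_noiseless_limit(self):
        rng = np.random.default_rng(9)
        n = 2_000
        G = rng.binomial(2, 0.3, size=(n, 10)).astype(float)
        y = G[:, 4] + 1e-4 * rng.normal(size=n)
        sig = single.cojo_select(G, y, None, p_threshold=1e-8)
        assert single.variance_explained(sig, G, y, None) > 0.99

    def test_matches_analytic_additive_variance(self):
        rng = np.random.default_rng(10)
        n = 5_000
        freqs = np.array([0.3, 0.1, 0.05])
        G = rng.binomial(2, freqs, size=(n, 3)).astype(float)
        betas = np.array([0.4, -0.5, 0.6])
        y = G @ betas + rng.normal(size=n)
        sig = single.cojo_select(G, y, None, p_threshold=1e-6)
        assert len(sig) == 3
        analytic = float(
            np.sum(2 * freqs * (1 - freqs) * betas**2)
            / (np.sum(2 * freqs * (1 - freqs) * betas**2) + 1.0)
        )
        got = single.variance_explained(sig, G, y, None)
        assert got == pytest.approx(analytic, rel=0.20)
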