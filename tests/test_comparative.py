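import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from _oracles import rma_perpendicular_oracle
from coralipm.comparative import (factorial_anova, plsr, ranged_major_axis)


def _standardize(M):
    return (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)


class TestPLSR:
    def _latent_data(self, n=30, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = rng.normal(size=n)
        X = np.outer(t, [1.0, -0.5, 2.0]) + noise * rng.normal(size=(n, 3))
        Y = np.outer(t, [0.7, 1.3, -0.2]) + noise * rng.normal(size=(n, 3))
        return X, Y

    def test_exact_latent_structure_first_component_captures_all(self):
        X, Y = self._latent_data(noise=0.0)
        res = plsr(X, Y, n_components=2)
        assert res.y_variance[0] == pytest.approx(1.0, abs=1e-8)
        assert res.ry2 == pytest.approx(1.0, abs=1e-8)

    def test_single_response_matches_svd_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        res = plsr(X, y, n_components=1)
        Xs = _standardize(X)
        ys = (y - y.mean()) / y.std(ddof=1)
        # first PLS weight = dominant left singular vector of X'Y
        w_oracle = Xs.T @ ys
        w_oracle /= np.linalg.norm(w_oracle)
        w = res.x_weights[:, 0]
        assert np.abs(w @ w_oracle) == pytest.approx(1.0, abs=1e-8)

    def test_agrees_with_sklearn_cross_check(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, Y = self._latent_data(noise=0.5, seed=2)
        res = plsr(X, Y, n_components=2)
        ref = sklearn.PLSRegression(n_components=2, scale=True).fit(X, Y)
        # scores agree up to sign per component
        for h in range(2):
            c = np.corrcoef(res.x_scores[:, h], ref.x_scores_[:, h])[0, 1]
            assert abs(abs(c) - 1.0) < 1e-6

    def test_row_permutation_leaves_variance_fractions_unchanged(self):
        X, Y = self._latent_data(noise=0.4, seed=3)
        res = plsr(X, Y)
        perm = np.random.default_rng(4).permutation(len(X))
        res_p = plsr(X[perm], Y[perm])
        np.testing.assert_allclose(res.x_variance, res_p.x_variance,
                                   atol=1e-10)
        np.testing.assert_allclose(res.y_variance, res_p.y_variance,
                                   atol=1e-10)

    def test_scores_orthogonal_and_x_reconstructed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 3))
        Y = rng.normal(size=(12, 3))
        res = plsr(X, Y, n_components=3)
        T = res.x_scores
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.max(np.abs(off)) < 1e-8
        Xs = _standardize(X)
        X_hat = T @ res.x_loadings.T
        np.testing.assert_allclose(X_hat, Xs, atol=1e-6)

    def test_constant_column_named_in_error(self):
        X = np.ones((10, 3))
        X[:, 1] = np.arange(10)
        X[:, 2] = np.arange(10) ** 2
        Xdf = pd.DataFrame(X, columns=["sst_mean", "sst_cv", "sst_beta"])
        with pytest.raises(ValueError, match="sst_mean"):
            plsr(Xdf, np.random.default_rng(6).normal(size=(10, 2)))


class TestRangedMajorAxis:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        res = ranged_major_axis(x, 2 * x)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_swap_inverts_slope(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        y = 1.7 * x + 0.2 * rng.normal(size=50)
        b = ranged_major_axis(x, y).slope
        b_swap = ranged_major_axis(y, x).slope
        assert b_swap == pytest.approx(1.0 / b, rel=1e-9)

    def test_matches_perpendicular_minimization_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            x = rng.normal(size=30)
            y = rng.uniform(0.5, 3.0) * x + rng.normal(size=30) * 0.5
            slope = ranged_major_axis(x, y).slope
            assert slope == pytest.approx(rma_perpendicular_oracle(x, y),
                                          abs=1e-6)

    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_affine_rescaling_transforms_slope_analytically(self, scale,
                                                            shift):
        rng = np.random.default_rng(9)
        x = rng.normal(size=25)
        y = 0.8 * x + 0.3 * rng.normal(size=25)
        b = ranged_major_axis(x, y).slope
        b_scaled = ranged_major_axis(x, scale * y + shift).slope
        assert b_scaled == pytest.approx(scale * b, rel=1e-6)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero range"):
            ranged_major_axis([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="3 paired"):
            ranged_major_axis([1.0, 2.0], [1.0, 2.0])


def _factorial_frame(effect=0.0, seed=0, per_cell=20, noise=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for country in ("Australia", "Japan"):
        for eco in ("tropical", "subtropical"):
            for strat in ("competitive", "stress_tolerant", "weedy"):
                mu = effect if eco == "tropical" else 0.0
                for _ in range(per_cell):
                    rows.append({"country": country, "ecoregion": eco,
                                 "strategy": strat,
                                 "value": mu + noise * rng.normal()})
    return pd.DataFrame(rows)


class TestFactorialAnova:
    def test_constant_response_has_no_significant_terms(self):
        df = _factorial_frame(effect=0.0, noise=0.0)
        df["value"] = 1.0
        res = factorial_anova(df)
        pvals = res.table["PR(>F)"].dropna()
        assert not (pvals < 0.05).any()

    def test_pure_ecoregion_effect_detected(self):
        df = _factorial_frame(effect=5.0, seed=1)
        res = factorial_anova(df)
        assert res.table.loc["C(ecoregion)", "PR(>F)"] < 0.001
        inter = [ix for ix in res.table.index if ":" in ix]
        assert (res.table.loc[inter, "PR(>F)"] > 0.01).all()
        # every within country x strategy ecoregion contrast present
        assert len(res.ecoregion_contrasts) == 6

    def test_single_factor_F_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 30)
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        df = pd.DataFrame({"value": np.r_[a, b],
                           "g": ["a"] * 30 + ["b"] * 30})
        fit = smf.ols("value ~ C(g)", data=df).fit()
        F = anova_lm(fit, typ=2).loc["C(g)", "F"]
        t = stats.ttest_ind(a, b).statistic
        assert F == pytest.approx(t ** 2, rel=1e-10)

    def test_balanced_design_ss_decomposition(self):
        df = _factorial_frame(effect=2.0, seed=3)
        res = factorial_anova(df)
        total_ss = float(((df["value"] - df["value"].mean()) ** 2).sum())
        assert res.table["sum_sq"].sum() == pytest.approx(total_ss, rel=1e-8)

    def test_empty_cell_reported(self):
        df = _factorial_frame(seed=4)
        df = df[~((df.country == "Japan") & (df.ecoregion == "tropical")
                  & (df.strategy == "weedy"))]
        with pytest.raises(ValueError, match="Japan"):
            factorial_anova(df)
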