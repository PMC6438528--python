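"""Inference layer: correlations, Fisher r-to-z differences, partial
correlation, stepwise regression, median splits, t-tests and ANOVA, each
checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from neuroaudience.inference import (
    dependent_correlation_difference,
    fisher_z_difference,
    median_split_models,
    oneway_anova_bonferroni,
    partial_correlation,
    pearson,
    stepwise_regression,
    two_sample_ttest,
)
from neuroaudience.recording import DegenerateSeriesError, NeuroaudienceError


def stepwise_oracle(X: pd.DataFrame, y: np.ndarray, p_enter=0.05, p_remove=0.10):
    """Independent re-implementation of forward/backward stepwise selection
    using plain least squares and t statistics (no statsmodels)."""

    def fit_p(cols):
        A = np.column_stack([np.ones(len(y))] + [X[c].to_numpy() for c in cols])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        dof = len(y) - A.shape[1]
        s2 = resid @ resid / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        t = beta / np.sqrt(np.diag(cov))
        return {c: 2 * stats.t.sf(abs(t[i + 1]), dof) for i, c in enumerate(cols)}

    included, order = [], []
    while True:
        changed = False
        outside = [c for c in X.columns if c not in included]
        best = None
        for c in outside:
            p = fit_p(included + [c])[c]
            if best is None or p < best[1]:
                best = (c, p)
        if best and best[1] < p_enter:
            included.append(best[0])
            order.append(best[0])
            changed = True
        while len(included) > 1:
            pvals = fit_p(included)
            removable = {c: p for c, p in pvals.items() if c != order[-1]}
            worst = max(removable, key=removable.get) if removable else None
            if worst and removable[worst] > p_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            return tuple(order), set(included)


class TestPearson:
    def test_identity_and_orthogonal(self, rng):
        x = rng.standard_normal(30)
        assert pearson(x, x).r == pytest.approx(1.0)
        y = rng.standard_normal(30)
        resid = y - (x @ (y - y.mean()) - 0) / 0.5  # not orthogonal; build properly
        xc = x - x.mean()
        resid = (y - y.mean()) - xc * ((y - y.mean()) @ xc) / (xc @ xc)
        assert abs(pearson(x, resid).r) < 1e-12

    def test_matches_covariance_formula_oracle(self, rng):
        x, y = rng.standard_normal((2, 49))
        res = pearson(x, y)
        r_oracle = np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert res.r == pytest.approx(r_oracle, rel=1e-12)
        t = r_oracle * np.sqrt(47 / (1 - r_oracle**2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 47), rel=1e-9)
        assert res.df == 47 and res.r2 == pytest.approx(r_oracle**2)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            pearson(np.ones(10), np.arange(10.0))


class TestFisherZ:
    def test_null_case_and_antisymmetry(self):
        res = fisher_z_difference(0.5, 30, 0.5, 40)
        assert res.z == 0.0 and res.p == pytest.approx(1.0)
        a = fisher_z_difference(0.7, 49, 0.2, 49)
        b = fisher_z_difference(0.2, 49, 0.7, 49)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_one_tailed_halves_p(self):
        two = fisher_z_difference(0.6, 40, 0.1, 40, tails="two")
        one = fisher_z_difference(0.6, 40, 0.1, 40, tails="one")
        assert one.p == pytest.approx(two.p / 2)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(NeuroaudienceError):
            fisher_z_difference(1.0, 20, 0.5, 20)

    def test_dependent_variant_properties(self):
        """The shared-sample (dependent-correlations) variant is zero at
        equality, antisymmetric, and sharper than the independent form when
        the non-shared variables correlate positively."""
        null = dependent_correlation_difference(0.5, 0.5, 0.3, 49)
        assert null.z == 0.0 and null.p == pytest.approx(1.0)
        a = dependent_correlation_difference(0.7, 0.2, 0.4, 49)
        b = dependent_correlation_difference(0.2, 0.7, 0.4, 49)
        assert a.z == pytest.approx(-b.z)
        indep = fisher_z_difference(0.7, 49, 0.2, 49)
        assert abs(a.z) > abs(indep.z)
        with pytest.raises(NeuroaudienceError):
            dependent_correlation_difference(0.5, 0.2, 1.5, 49)

    def test_dependent_variant_calibrated_under_null(self):
        """Empirical false-positive rate near 5% for the shared-sample test
        on simulated trivariate normal draws with equal true correlations."""
        rng = np.random.default_rng(11)
        cov = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.3], [0.4, 0.3, 1.0]])
        L = np.linalg.cholesky(cov)
        rejections = 0
        n_rep = 800
        for _ in range(n_rep):
            x = (L @ rng.standard_normal((3, 49)))
            r_jk = np.corrcoef(x[0], x[1])[0, 1]
            r_jh = np.corrcoef(x[0], x[2])[0, 1]
            r_kh = np.corrcoef(x[1], x[2])[0, 1]
            if dependent_correlation_difference(r_jk, r_jh, r_kh, 49).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestPartialCorrelation:
    def test_unrelated_control_leaves_r(self, rng):
        x = rng.standard_normal(200)
        y = 0.5 * x + rng.standard_normal(200)
        # control orthogonalized jointly against both inputs
        z = rng.standard_normal(200)
        A = np.column_stack([np.ones(200), x, y])
        beta, *_ = np.linalg.lstsq(A, z, rcond=None)
        z = z - A @ beta
        assert partial_correlation(x, y, z).r_partial == pytest.approx(
            pearson(x, y).r, abs=1e-10
        )

    def test_control_equal_to_input_rejected(self, rng):
        x, y = rng.standard_normal((2, 30))
        with pytest.raises(NeuroaudienceError):
            partial_correlation(x, y, y)

    def test_matches_residual_correlation_oracle(self, rng):
        x, y, z = rng.standard_normal((3, 49))
        res = partial_correlation(x, y, z)

        def residuals(v, w):
            A = np.column_stack([np.ones(len(w)), w])
            beta, *_ = np.linalg.lstsq(A, v, rcond=None)
            return v - A @ beta

        oracle = np.corrcoef(residuals(x, z), residuals(y, z))[0, 1]
        assert res.r_partial == pytest.approx(oracle, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y, z = rng.standard_normal((3, 49))
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        res = partial_correlation(x, y, z)
        assert res.r_partial == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)


class TestStepwise:
    def test_single_informative_predictor_entered(self, rng):
        n = 49
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        y = 2.0 * X["b"] + 0.3 * rng.standard_normal(n)
        res = stepwise_regression(X, y)
        assert res.entered == ("b",)
        assert res.std_betas["b"] == pytest.approx(
            pearson(X["b"], y).r, rel=1e-9
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_matches_independent_selection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 49
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        y = (0.5 * X["a"] + 0.3 * X["c"] + rng.standard_normal(n)).to_numpy()
        res = stepwise_regression(X, y)
        order, final = stepwise_oracle(X, y)
        assert res.entered == order
        assert set(res.entered) == final

    def test_thresholds_of_one_reproduce_full_ols(self, rng):
        import statsmodels.api as sm

        n = 30
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        y = rng.standard_normal(n)
        res = stepwise_regression(X, y, p_enter=1.0, p_remove=1.0)
        assert set(res.entered) == {"a", "b", "c"}
        full = sm.OLS(y, sm.add_constant(X)).fit()
        assert res.r2 == pytest.approx(full.rsquared, rel=1e-12)
        assert res.adj_r2 == pytest.approx(full.rsquared_adj, rel=1e-12)

    def test_standardized_betas_scale_invariant(self, rng):
        n = 60
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        y = X["a"] - 0.5 * X["b"] + 0.5 * rng.standard_normal(n)
        raw = stepwise_regression(X, y)
        Xz = (X - X.mean()) / X.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        z = stepwise_regression(Xz, yz)
        for c in raw.entered:
            assert raw.std_betas[c] == pytest.approx(z.std_betas[c], rel=1e-9)

    def test_pure_noise_gives_flagged_empty_model(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 2)), columns=["a", "b"])
        y = np.ones(40) + 1e-6 * rng.standard_normal(40)
        res = stepwise_regression(X, y, p_enter=1e-9)
        assert res.empty and res.entered == ()


class TestMedianSplit:
    def test_49_rows_split_25_low_24_high(self, rng):
        table = pd.DataFrame(
            {
                "split": rng.permutation(np.arange(49.0)),
                "y": rng.standard_normal(49),
                "a": rng.standard_normal(49),
                "b": rng.standard_normal(49),
            }
        )
        res = median_split_models(table, "split", "y", ["a", "b"])
        assert (res.n_low, res.n_high) == (25, 24)

    def test_coupling_only_in_high_half_recovered(self, rng):
        n = 60
        split = np.r_[np.zeros(30), np.ones(30)]
        a = rng.standard_normal(n)
        y = np.where(split > 0, 2.0 * a, 0.0) + 0.4 * rng.standard_normal(n)
        table = pd.DataFrame({"split": split, "y": y, "a": a,
                              "b": rng.standard_normal(n)})
        res = median_split_models(table, "split", "y", ["a", "b"])
        assert "a" in res.high.entered
        assert "a" not in (res.low.entered if res.low else ())

    def test_constant_split_variable_rejected(self, rng):
        table = pd.DataFrame({"split": np.ones(20), "y": rng.standard_normal(20),
                              "a": rng.standard_normal(20)})
        with pytest.raises(DegenerateSeriesError):
            median_split_models(table, "split", "y", ["a"])


class TestTTestAnova:
    def test_identical_groups_t_zero(self):
        res = two_sample_ttest([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_df_bookkeeping(self, rng):
        res = two_sample_ttest(rng.standard_normal(49), rng.standard_normal(44))
        assert res.df == 91

    def test_matches_textbook_formula(self, rng):
        a = rng.standard_normal(20) + 0.5
        b = rng.standard_normal(25)
        res = two_sample_ttest(a, b)
        sp = np.sqrt(((19 * a.var(ddof=1)) + (24 * b.var(ddof=1))) / 43)
        t_oracle = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 20 + 1 / 25))
        assert res.t == pytest.approx(t_oracle, rel=1e-12)

    def test_identical_groups_f_zero(self):
        res = oneway_anova_bonferroni(
            {"a": [1.0, 2, 3], "b": [1.0, 2, 3]}, transform=None
        )
        assert res.f == pytest.approx(0.0, abs=1e-12)

    def test_episode_scale_df(self, rng):
        groups = {f"ep{i}": rng.random(60) for i in range(9)}
        res = oneway_anova_bonferroni(groups)
        assert (res.df_between, res.df_within) == (8, 531)

    def test_two_group_f_equals_t_squared(self, rng):
        a = rng.random(15)
        b = rng.random(18)
        res = oneway_anova_bonferroni({"a": a, "b": b}, transform=None)
        t = two_sample_ttest(a, b)
        assert res.f == pytest.approx(t.t**2, rel=1e-10)
        assert res.p == pytest.approx(t.p, rel=1e-10)

    def test_sqrt_transform_rejects_negative(self):
        with pytest.raises(NeuroaudienceError):
            oneway_anova_bonferroni({"a": [-1.0, 2], "b": [1.0, 2]})

    def test_bonferroni_capped_and_symmetric(self, rng):
        groups = {k: rng.random(10) for k in "abcd"}
        res = oneway_anova_bonferroni(groups, transform=None)
        m = res.pairwise_p.to_numpy()
        assert np.nanmax(m) <= 1.0
        np.testing.assert_allclose(m, m.T)


class TestNullCalibration:
    def test_pearson_false_positive_rate_nominal(self):
        """Under a global null (independent vectors, n = 49), the two-tailed
        Pearson test rejects at the nominal 5% level (1000 replicates)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(1000):
            x, y = rng.standard_normal((2, 49))
            if pearson(x, y).p < 0.05:
                rejections += 1
        assert 0.035 <= rejections / 1000 <= 0.065

    def test_fisher_false_positive_rate_nominal(self):
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(1000):
            x1, y1, x2, y2 = rng.standard_normal((4, 49))
            r1, r2 = pearson(x1, y1).r, pearson(x2, y2).r
            if fisher_z_difference(r1, 49, r2, 49).p < 0.05:
                rejections += 1
        assert 0.035 <= rejections / 1000 <= 0.065
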