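"""Precision-weighted DE: the log-CPM transform, mean-variance weights,
weighted least squares against a normal-equations oracle, and the
empirical-Bayes moderation including its reduction to ordinary t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agingsig.aging import AgeAssociationRegression
from agingsig.de import (
    VoomLimma,
    call_degs,
    ebayes_moderate,
    estimate_prior,
    log_cpm,
    voom_weights,
    weighted_fit,
)


def frame(arr, prefix="g"):
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"s{i}" for i in range(arr.shape[1])])


def design_frame(arr, names):
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=names)


def make_design(n, rng, condition=True):
    cols = [np.ones(n)]
    names = ["intercept"]
    if condition:
        cols.append(np.repeat([0.0, 1.0], [n - n // 2, n // 2]))
        names.append("condition")
    cols.append(rng.normal(size=n))
    names.append("cov")
    return design_frame(np.column_stack(cols), names)


class TestLogCpm:
    def test_zero_count_value(self):
        counts = frame(np.array([[0]]))
        out = log_cpm(counts, pd.Series([1e6]))
        assert out.iloc[0, 0] == pytest.approx(np.log2(0.5e6 / (1e6 + 1)), abs=1e-9)

    def test_full_library_approaches_log2_million(self):
        lib = 1e9
        out = log_cpm(frame(np.array([[lib]])), pd.Series([lib]))
        assert out.iloc[0, 0] == pytest.approx(np.log2(1e6), abs=1e-4)

    def test_scale_invariance_for_large_counts(self, rng):
        counts = frame(rng.integers(100_000, 500_000, size=(20, 6)).astype(float))
        lib = counts.sum(axis=0)
        a = log_cpm(counts, lib)
        b = log_cpm(2 * counts, 2 * lib)
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 1e-5

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="nonnegative"):
            log_cpm(frame(np.array([[-1.0]])), pd.Series([10.0]))
        with pytest.raises(ValueError, match="library"):
            log_cpm(frame(np.array([[1.0]])), pd.Series([0.0]))


class TestVoomWeights:
    def test_homoskedastic_data_gives_flat_weights(self, rng):
        # equal-mean, equal-dispersion genes: weights nearly constant
        counts = frame(rng.poisson(500.0, size=(300, 40)).astype(float))
        design = make_design(40, rng)
        fit = voom_weights(counts, design)
        w = fit.weights.to_numpy()
        assert np.isfinite(w).all() and (w > 0).all()
        assert w.std() / w.mean() < 0.2

    def test_engineered_trend_orders_weights_by_abundance(self, rng):
        """Log-scale SD decreasing with abundance -> weights increase with
        mean log-count."""
        n, genes = 30, 400
        means = np.geomspace(10, 10000, genes)
        sds = 1.5 / np.log10(means)  # decreasing in abundance
        y = np.log2(means)[:, None] + sds[:, None] * rng.normal(size=(genes, n))
        counts = frame(np.maximum(2 ** y, 0.0))
        design = make_design(n, rng)
        fit = voom_weights(counts, design)
        mean_w = fit.weights.mean(axis=1).to_numpy()
        mean_lc = fit.log_cpm.mean(axis=1).to_numpy()
        rho = stats.spearmanr(mean_lc, mean_w).statistic
        assert rho > 0.8

    def test_degenerate_equal_counts_stay_finite(self, rng):
        counts = frame(np.full((20, 10), 100.0))
        design = make_design(10, rng)
        fit = voom_weights(counts, design)
        assert np.isfinite(fit.weights.to_numpy()).all()

    def test_too_few_genes_warns_unit_weights(self, rng):
        counts = frame(rng.poisson(100.0, size=(5, 12)).astype(float))
        with pytest.warns(UserWarning, match="fewer than 10"):
            fit = voom_weights(counts, make_design(12, rng))
        assert (fit.weights.to_numpy() == 1.0).all()


class TestWeightedFit:
    def test_unit_weights_reduce_to_ols(self, rng):
        n, genes = 25, 8
        design = make_design(n, rng)
        y = frame(rng.normal(size=(genes, n)))
        w = frame(np.ones((genes, n)))
        coef, se_u, s2, df = weighted_fit(y, w, design)
        ols = AgeAssociationRegression(age_col="condition").fit(design, y)
        assert np.abs(coef.to_numpy() - ols.coef_.to_numpy()).max() < 1e-10
        assert np.abs((se_u.to_numpy() * np.sqrt(s2.to_numpy())[:, None])
                      - ols.se_.to_numpy()).max() < 1e-10

    def test_matches_weighted_normal_equations_oracle(self, rng):
        n, p, genes = 12, 3, 6
        x = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        design = design_frame(x, ["intercept", "condition", "cov"])
        y = rng.normal(size=(genes, n))
        w = rng.uniform(0.2, 5.0, size=(genes, n))
        coef, se_u, s2, df = weighted_fit(frame(y), frame(w), design)
        for g in range(genes):
            W = np.diag(w[g])
            beta = np.linalg.inv(x.T @ W @ x) @ x.T @ W @ y[g]
            assert np.abs(coef.iloc[g].to_numpy() - beta).max() < 1e-8

    def test_huge_weight_approaches_interpolation(self, rng):
        n = 10
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        design = design_frame(x, ["intercept", "cov"])
        y = rng.normal(size=(1, n))
        w = np.ones((1, n))
        w[0, 0] = 1e8
        coef, _, _, _ = weighted_fit(frame(y), frame(w), design)
        fitted0 = coef.iloc[0] @ x[0]
        assert abs(fitted0 - y[0, 0]) < 1e-4

    def test_nonpositive_weights_rejected(self, rng):
        design = make_design(8, rng)
        with pytest.raises(ValueError, match="weights"):
            weighted_fit(frame(np.ones((2, 8))), frame(np.zeros((2, 8))), design)


class TestEbayes:
    def _fit(self, rng, genes=40, n=20):
        design = make_design(n, rng)
        y = frame(rng.normal(size=(genes, n)))
        w = frame(np.ones((genes, n)))
        return weighted_fit(y, w, design), design

    def test_d0_zero_reproduces_ordinary_t(self, rng):
        (coef, se_u, s2, df), design = self._fit(rng)
        tab = ebayes_moderate(coef, se_u, s2, df, prior=(0.0, 1.0))
        t_ord = coef["condition"] / (se_u["condition"] * np.sqrt(s2))
        assert np.abs(tab["t"] - t_ord).max() < 1e-12
        p_ord = 2 * stats.t.sf(np.abs(t_ord), df)
        assert np.abs(tab["p"] - p_ord).max() < 1e-12

    def test_identical_variances_are_fixed_point(self, rng):
        (coef, se_u, s2, df), design = self._fit(rng)
        s2_const = pd.Series(2.0, index=s2.index)
        tab = ebayes_moderate(coef, se_u, s2_const, df, prior=(7.0, 2.0))
        t_expected = coef["condition"] / (se_u["condition"] * np.sqrt(2.0))
        assert np.abs(tab["t"] - t_expected).max() < 1e-12

    def test_prior_recovery_from_scaled_chisquare(self, rng):
        d0, s0sq, d, genes = 4.0, 1.0, 16, 5000
        sigma2 = s0sq * d0 / rng.chisquare(d0, genes)
        s2 = sigma2 * rng.chisquare(d, genes) / d
        d0_hat, s0_hat = estimate_prior(s2, d)
        assert abs(d0_hat - d0) / d0 < 0.5
        assert abs(s0_hat - s0sq) / s0sq < 0.2

    def test_no_excess_variance_falls_back_to_full_shrinkage(self, rng):
        s2 = np.full(50, 3.0)
        with pytest.warns(UserWarning, match="full shrinkage"):
            d0, s0 = estimate_prior(s2, 10)
        assert np.isinf(d0)

    def test_moderation_shrinks_toward_prior(self, rng):
        n, genes = 20, 100
        design = make_design(n, rng)
        scales = rng.gamma(2.0, 1.0, genes)  # heterogeneous true variances
        y = frame(np.sqrt(scales)[:, None] * rng.normal(size=(genes, n)))
        w = frame(np.ones((genes, n)))
        coef, se_u, s2, df = weighted_fit(y, w, design)
        tab = ebayes_moderate(coef, se_u, s2, df)
        assert tab.attrs["d0"] > 0
        # posterior variances lie between each gene's s2 and the prior
        s2p = (tab.attrs["d0"] * tab.attrs["s0_sq"] + df * s2) / (tab.attrs["d0"] + df)
        lo = np.minimum(s2, tab.attrs["s0_sq"])
        hi = np.maximum(s2, tab.attrs["s0_sq"])
        assert ((s2p >= lo - 1e-12) & (s2p <= hi + 1e-12)).all()


class TestCallDegs:
    def test_empty_table(self):
        tab = pd.DataFrame(columns=["logFC", "fdr"])
        up, down = call_degs(tab)
        assert up == set() and down == set()

    def test_threshold_is_strict(self):
        tab = pd.DataFrame({"logFC": [1.0, 1.0, -1.0],
                            "fdr": [0.05, 0.049, 0.01]},
                           index=["a", "b", "c"])
        up, down = call_degs(tab, 0.05)
        assert up == {"b"} and down == {"c"}

    def test_strong_effect_detected_across_seeds(self):
        """A planted two-fold disease shift lands in the up-set in >= 95%
        of independent small simulations."""
        hits = 0
        runs = 60
        for s in range(runs):
            rng = np.random.default_rng(1000 + s)
            n, genes = 40, 60
            cond = np.repeat([0.0, 1.0], n // 2)
            design = design_frame(np.column_stack([np.ones(n), cond]),
                                  ["intercept", "condition"])
            mu = np.full((genes, n), 200.0)
            mu[0] *= 2 ** cond  # gene 0: true up-regulation
            counts = frame(rng.poisson(mu).astype(float))
            model = VoomLimma().fit(design, counts)
            up, down = call_degs(model.table_)
            hits += "g0" in up
        assert hits / runs >= 0.95


class TestVoomLimmaEstimator:
    def test_reduction_to_ordinary_ols_ttest(self, rng):
        """Unit weights + d0 = 0 turn the DE stage into the plain per-gene
        OLS t-test from the aging fitter on the same log-CPM data."""
        n, genes = 30, 50
        design = make_design(n, rng)
        counts = frame(rng.poisson(300.0, size=(genes, n)).astype(float))
        y = log_cpm(counts)
        w = frame(np.ones((genes, n)))
        coef, se_u, s2, df = weighted_fit(y, w, design)
        tab = ebayes_moderate(coef, se_u, s2, df, prior=(0.0, 1.0))
        ols = AgeAssociationRegression(age_col="condition").fit(design, y)
        assert np.abs(tab["t"].to_numpy() - ols.table_["t"].to_numpy()).max() < 1e-10
        assert np.abs(tab["p"].to_numpy() - ols.table_["p"].to_numpy()).max() < 1e-10

    def test_all_zero_genes_dropped(self, rng):
        n = 20
        design = make_design(n, rng)
        counts = rng.poisson(100.0, size=(30, n)).astype(float)
        counts[5] = 0.0
        model = VoomLimma().fit(design, frame(counts))
        assert "g5" not in model.table_.index
        assert len(model.table_) == 29

    def test_get_set_params_roundtrip(self):
        model = VoomLimma(fdr_threshold=0.1, span=0.4)
        params = model.get_params()
        assert params["fdr_threshold"] == 0.1
        clone = VoomLimma().set_params(**params)
        assert clone.span == 0.4
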