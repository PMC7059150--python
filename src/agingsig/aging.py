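"""Per-gene covariate-adjusted age-association regression.

For gene j and sample i the model is

    Y_ij = beta_j + gamma_j*Age_i + delta_j*Sex_i
           + sum_k mu_jk*Genotype_ik + sum_k alpha_jk*PC_ik
           + theta_j*RIN_i + lambda_j*PMI_i + eps_ij,

fitted by ordinary least squares gene-by-gene (vectorized over genes since
the design is shared). The age coefficient gamma_j is tested two-sided; an
"aging gene" is one whose age term passes Benjamini–Hochberg FDR <= 0.01.
Expression principal components serve as data-driven technical covariates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import linalg as scipy_linalg
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_AGING_FDR = 0.01


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def preprocess_expression(
    tpm: pd.DataFrame,
    min_value: float = 0.1,
    min_fraction: float = 0.2,
) -> pd.DataFrame:
    """log2(TPM + 1) after dropping weakly expressed genes.

    A gene is retained only if its value exceeds ``min_value`` in at least
    ``min_fraction`` of samples. Raises if nothing survives.
    """
    if (tpm.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    expressed = (tpm > min_value).mean(axis=1) >= min_fraction
    n_dropped = int((~expressed).sum())
    logger.info(
        "expression filter: kept %d/%d genes (dropped %d below %g in %g%% of samples)",
        int(expressed.sum()), len(tpm), n_dropped, min_value, 100 * min_fraction,
    )
    if not expressed.any():
        raise ValueError("all genes removed by the expression filter")
    return np.log2(tpm.loc[expressed] + 1.0)


def compute_expression_pcs(log_expr: pd.DataFrame, n_pcs: int) -> pd.DataFrame:
    """Sample scores of the top principal components of gene-centered
    log-expression.

    The sign of each component is fixed by making its largest-|loading| gene
    positive, so results are deterministic. ``n_pcs <= 0`` returns an empty
    frame (no PC adjustment).
    """
    if n_pcs <= 0:
        return pd.DataFrame(index=log_expr.columns)
    n_samples = log_expr.shape[1]
    if n_pcs >= n_samples:
        raise ValueError(f"n_pcs={n_pcs} must be < n_samples={n_samples}")
    x = log_expr.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = []
    for k in range(n_pcs):
        loading = u[:, k]
        flip = np.sign(loading[np.argmax(np.abs(loading))]) or 1.0
        scores.append(flip * s[k] * vt[k])
    return pd.DataFrame(
        np.column_stack(scores),
        index=log_expr.columns,
        columns=[f"PC{k + 1}" for k in range(n_pcs)],
    )


def build_design(
    samples: pd.DataFrame,
    donors: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    include_pmi: bool = True,
) -> pd.DataFrame:
    """Assemble the regression design (one row per sample, sample-id index).

    Columns: intercept, age, sex (male = 1), genotype covariates, PC scores,
    rin, pmi. Raises on missing values.
    """
    merged = samples.merge(donors, on="donor_id", how="left", validate="one_to_one")
    design = pd.DataFrame(index=merged["sample_id"])
    design["intercept"] = 1.0
    design["age"] = merged["age"].to_numpy()
    design["sex"] = (merged["sex"] == "male").to_numpy().astype(float)
    for col in donors.columns:
        if col.startswith("genotype_"):
            design[col] = merged[col].to_numpy()
    if pcs is not None and pcs.shape[1]:
        for col in pcs.columns:
            design[col] = pcs[col].reindex(design.index).to_numpy()
    design["rin"] = merged["rin"].to_numpy()
    if include_pmi:
        design["pmi"] = merged["pmi"].to_numpy()
    if design.isna().to_numpy().any():
        bad = design.columns[design.isna().any()].tolist()
        raise ValueError(f"design matrix has missing values in columns {bad}")
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the dependent columns via QR pivoting
        _, r, piv = scipy_linalg.qr(x, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        keep = diag > diag[0] * 1e-10
        bad = sorted(design.columns[piv[i]] for i in range(len(keep)) if not keep[i])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


class AgeAssociationRegression(BaseEstimator):
    """Per-gene OLS of log-expression on the aging design.

    Parameters
    ----------
    age_col : name of the design column tested as the age coefficient.
    fdr_threshold : BH-FDR cutoff below/at which a gene is called an aging
        gene (default 0.01).

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : DataFrame (genes x covariates) of OLS estimates.
    se_ : DataFrame of standard errors.
    sigma2_ : per-gene residual variance (Series).
    df_resid_ : residual degrees of freedom (int).
    zero_variance_ : boolean Series flagging genes with constant expression.
    table_ : the aging-gene table for ``age_col`` (see :meth:`test_covariate`).
    """

    def __init__(self, age_col: str = "age", fdr_threshold: float = DEFAULT_AGING_FDR):
        self.age_col = age_col
        self.fdr_threshold = fdr_threshold

    def fit(self, X: pd.DataFrame, Y: pd.DataFrame) -> "AgeAssociationRegression":
        """Fit every gene.

        X : design matrix, samples x covariates (including an intercept).
        Y : log-expression, genes x samples, columns aligned to X's rows.
        """
        if list(X.index) != list(Y.columns):
            Y = Y.loc[:, X.index]
        x = X.to_numpy(dtype=float)
        y = Y.to_numpy(dtype=float)
        n, p = x.shape
        if n <= p + 1:
            raise ValueError(f"need n_samples > n_covariates + 1, got {n} <= {p + 1}")
        _check_full_rank(X)
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = y @ x @ xtx_inv  # genes x p
        resid = y - beta @ x.T
        df = n - p
        rss = np.einsum("ij,ij->i", resid, resid)
        sigma2 = rss / df
        zero_var = y.var(axis=1) == 0
        se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))

        self.design_columns_ = list(X.columns)
        self.coef_ = pd.DataFrame(beta, index=Y.index, columns=X.columns)
        self.se_ = pd.DataFrame(se, index=Y.index, columns=X.columns)
        self.sigma2_ = pd.Series(sigma2, index=Y.index, name="sigma2")
        self.df_resid_ = df
        self.zero_variance_ = pd.Series(zero_var, index=Y.index, name="zero_variance")
        if zero_var.any():
            logger.warning("%d genes have zero variance; their p-values are set to 1",
                           int(zero_var.sum()))
        self.table_ = self.test_covariate(self.age_col, fdr_threshold=self.fdr_threshold)
        return self

    def test_covariate(self, name: str, fdr_threshold: float | None = None) -> pd.DataFrame:
        """Two-sided t-test plus BH-FDR for any fitted coefficient.

        Returns a per-gene table: estimate, se, t, p, fdr, direction, and a
        significance flag at ``fdr_threshold``.
        """
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted")
        if name not in self.coef_.columns:
            raise KeyError(
                f"unknown coefficient {name!r}; available: {list(self.coef_.columns)}"
            )
        if fdr_threshold is None:
            fdr_threshold = self.fdr_threshold
        est = self.coef_[name].to_numpy()
        se = self.se_[name].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), self.df_resid_)
        p[self.zero_variance_.to_numpy()] = 1.0
        fdr = bh_fdr(p)
        return pd.DataFrame(
            {
                "estimate": est,
                "se": se,
                "t": t,
                "p": p,
                "fdr": fdr,
                "direction": np.sign(est).astype(int),
                "significant": fdr <= fdr_threshold,
                "zero_variance": self.zero_variance_.to_numpy(),
            },
            index=self.coef_.index,
        )


def fit_age_regression(
    log_expr: pd.DataFrame,
    design: pd.DataFrame,
    fdr_threshold: float = DEFAULT_AGING_FDR,
    age_col: str = "age",
) -> pd.DataFrame:
    """Thin wrapper: fit the per-gene model and return the aging-gene table
    (columns estimate/se/t/p/fdr/direction/significant, gene-id index)."""
    model = AgeAssociationRegression(age_col=age_col, fdr_threshold=fdr_threshold)
    model.fit(design, log_expr)
    return model.table_
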