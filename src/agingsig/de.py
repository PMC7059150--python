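"""Precision-weighted differential expression between disease and healthy
cohorts.

Counts are transformed to log2-CPM; a mean-variance trend is fitted by lowess
to (average log-count, sqrt residual SD) across genes; per-observation
precision weights are the predicted sqrt-SD to the power -4; genes are fitted
by weighted least squares against a design of condition + sex + age + RIN +
ischemic time + genotype covariates; residual variances are shrunk toward a
pooled prior estimated by moment-matching the log residual variances against
the scaled-F model (prior df d0, prior variance s0^2), giving moderated
t-statistics with d0 + d_g degrees of freedom. Genes with BH-FDR < 0.05 on
the condition coefficient are called DEGs.

This is the classical precision-weights / variance-moderation approach for
RNA-seq linear models, implemented here directly on numpy/scipy/statsmodels
primitives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

from .aging import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_DEG_FDR = 0.05
_SQRT_SD_FLOOR = 1e-4


def log_cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """log2 counts-per-million with the 0.5 / +1 offsets:
    log2((count + 0.5) / (libsize + 1) * 1e6)."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lib = np.asarray(library_sizes, dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    return np.log2((counts + 0.5).div(lib + 1.0, axis=1) * 1e6)


def build_de_design(
    samples: pd.DataFrame,
    donors: pd.DataFrame,
    condition: pd.Series,
) -> pd.DataFrame:
    """Design for the disease-vs-healthy contrast: intercept, condition
    (disease = 1), sex, age, RIN, ischemic time, genotype covariates.

    ``condition`` is indexed by sample id with values {0, 1}; both levels
    must be present.
    """
    merged = samples.merge(donors, on="donor_id", how="left", validate="one_to_one")
    design = pd.DataFrame(index=merged["sample_id"])
    design["intercept"] = 1.0
    cond = condition.reindex(design.index).astype(float)
    if cond.isna().any():
        raise ValueError("condition is missing for some samples")
    if cond.nunique() < 2:
        raise ValueError("both condition levels must be present")
    design["condition"] = cond.to_numpy()
    design["sex"] = (merged["sex"] == "male").to_numpy().astype(float)
    design["age"] = merged["age"].to_numpy()
    design["rin"] = merged["rin"].to_numpy()
    design["ischemic_time"] = merged["ischemic_time"].to_numpy()
    for col in donors.columns:
        if col.startswith("genotype_"):
            design[col] = merged[col].to_numpy()
    if design.isna().to_numpy().any():
        bad = design.columns[design.isna().any()].tolist()
        raise ValueError(f"DE design has missing values in columns {bad}")
    return design


@dataclass
class VoomFit:
    """Mean-variance trend output: the log-CPM matrix, per-observation
    precision weights, and the (mean log-count, sqrt-SD) trend points."""

    log_cpm: pd.DataFrame
    weights: pd.DataFrame
    trend_x: np.ndarray
    trend_y: np.ndarray


def voom_weights(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    span: float = 0.5,
) -> VoomFit:
    """Estimate per-observation precision weights from the mean-variance
    trend of log-counts.

    Per gene, an unweighted OLS fit gives the residual SD; lowess (span 0.5)
    smooths sqrt(residual SD) against average log-count; each observation's
    fitted log-count is interpolated through the trend and the predicted
    sqrt-SD (floored at a small positive constant) is raised to the power -4
    to give its weight. With fewer than 10 genes the trend is not estimable
    and unit weights are returned with a warning.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    y = log_cpm(counts)
    x = design.to_numpy(dtype=float)
    n, p = x.shape[0], np.linalg.matrix_rank(design.to_numpy(dtype=float))
    ymat = y.to_numpy(dtype=float)

    xtx_inv_xt = np.linalg.pinv(x)
    beta = ymat @ xtx_inv_xt.T
    fitted = beta @ x.T
    resid = ymat - fitted
    df = n - p
    sd = np.sqrt(np.einsum("ij,ij->i", resid, resid) / df)

    if len(counts) < 10:
        warnings.warn("fewer than 10 genes: mean-variance trend not fitted, "
                      "unit weights used", stacklevel=2)
        w = pd.DataFrame(1.0, index=y.index, columns=y.columns)
        return VoomFit(y, w, np.array([]), np.array([]))

    # average log2 count per gene: mean log-CPM shifted back to count scale
    mean_log_count = ymat.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sqrt_sd = np.sqrt(sd)
    smooth = lowess(sqrt_sd, mean_log_count, frac=span, it=3, return_sorted=True)
    tx, ty = smooth[:, 0], smooth[:, 1]
    # fitted log-count per observation
    fitted_log_count = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_log_count, tx, ty)  # flat extrapolation at ends
    pred = np.where(np.isfinite(pred), pred, _SQRT_SD_FLOOR)
    pred = np.maximum(pred, _SQRT_SD_FLOOR)
    w = pred ** -4.0
    return VoomFit(y, pd.DataFrame(w, index=y.index, columns=y.columns), tx, ty)


def weighted_fit(
    log_cpm_matrix: pd.DataFrame,
    weights: pd.DataFrame,
    design: pd.DataFrame,
):
    """Per-gene weighted least squares.

    Returns ``(coef, se_unscaled, sigma2, df_resid)``: coefficient estimates,
    unscaled standard errors (multiply by the residual SD to get classical
    SEs), weighted residual variance s2_g = weighted RSS / (n - rank), and
    the residual df.
    """
    x = design.to_numpy(dtype=float)
    y = log_cpm_matrix.to_numpy(dtype=float)
    w = weights.to_numpy(dtype=float)
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be positive and finite")
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise ValueError("DE design matrix is rank deficient")
    df = n - rank

    # batched weighted normal equations: per gene, (X'WX) b = X'Wy
    xtwx = np.einsum("gi,ij,ik->gjk", w, x, x)
    xtwy = np.einsum("gi,ij,gi->gj", w, x, y)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    resid = y - beta @ x.T
    rss = np.einsum("gi,gi->g", w, resid**2)
    sigma2 = rss / df
    xtwx_inv = np.linalg.inv(xtwx)
    unscaled = np.sqrt(np.diagonal(xtwx_inv, axis1=1, axis2=2))

    coef = pd.DataFrame(beta, index=log_cpm_matrix.index, columns=design.columns)
    se_unscaled = pd.DataFrame(unscaled, index=log_cpm_matrix.index, columns=design.columns)
    return coef, se_unscaled, pd.Series(sigma2, index=log_cpm_matrix.index), df


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (prior df d0, prior variance s0^2) from residual
    variances.

    Under the hierarchical model, log(s2_g) follows a shifted log-F
    distribution whose mean and variance are expressible in digamma/trigamma
    terms; matching the empirical moments and inverting the trigamma yields
    d0, then s0^2. If the excess variance of log(s2) is non-positive the
    variances are effectively identical and d0 = inf (full shrinkage) is
    returned with a warning.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = (s2 > 0) & np.isfinite(s2)
    if ok.sum() < 10:
        raise ValueError("need >= 10 genes with positive residual variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        warnings.warn("no excess variance in log s2; using d0 = inf (full shrinkage)",
                      stacklevel=2)
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0sq


def ebayes_moderate(
    coef: pd.DataFrame,
    se_unscaled: pd.DataFrame,
    sigma2: pd.Series,
    df: float,
    contrast: str = "condition",
    fdr_threshold: float = DEFAULT_DEG_FDR,
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Moderated t-statistics for one coefficient via variance shrinkage.

    s2_post = (d0*s0^2 + df*s2_g) / (d0 + df); t_mod = b_g / (se_unscaled *
    s_post), with d0 + df degrees of freedom, then BH-FDR. ``prior`` may pin
    (d0, s0^2) — d0 = 0 reproduces ordinary per-gene t-tests exactly.

    Returns the DEG table: logFC, t, p, fdr, direction, is_deg, plus the
    shrinkage hyperparameters as attrs ``d0`` and ``s0_sq``.
    """
    s2 = sigma2.to_numpy(dtype=float)
    if prior is None:
        d0, s0sq = estimate_prior(s2, df)
    else:
        d0, s0sq = prior
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = d0 + df
    b = coef[contrast].to_numpy(dtype=float)
    u = se_unscaled[contrast].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = b / (u * np.sqrt(s2_post))
    t_mod = np.nan_to_num(t_mod, nan=0.0, posinf=0.0, neginf=0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    fdr = bh_fdr(p)
    table = pd.DataFrame(
        {
            "logFC": b,
            "t": t_mod,
            "p": p,
            "fdr": fdr,
            "direction": np.sign(b).astype(int),
            "is_deg": fdr < fdr_threshold,
        },
        index=coef.index,
    )
    table.attrs["d0"] = float(d0)
    table.attrs["s0_sq"] = float(s0sq)
    table.attrs["df_resid"] = float(df)
    return table


def call_degs(table: pd.DataFrame, threshold: float = DEFAULT_DEG_FDR):
    """Split significant DEGs by direction: fdr strictly below threshold and
    nonzero log-fold-change. Returns ``(up, down)`` gene-id sets."""
    sig = table["fdr"] < threshold
    up = set(table.index[sig & (table["logFC"] > 0)])
    down = set(table.index[sig & (table["logFC"] < 0)])
    return up, down


class VoomLimma(BaseEstimator):
    """Estimator wrapper for the full precision-weighted DE stage.

    fit(X, Y) with X the DE design (samples x covariates, including the
    ``condition`` column) and Y the raw counts (genes x samples) runs the
    log-CPM transform, weight estimation, weighted fit and moderation.

    Attributes after fit: ``voom_``, ``coef_``, ``sigma2_``, ``df_resid_``,
    ``d0_``, ``s0_sq_``, ``table_``.
    """

    def __init__(
        self,
        contrast: str = "condition",
        fdr_threshold: float = DEFAULT_DEG_FDR,
        span: float = 0.5,
        prior: tuple[float, float] | None = None,
    ):
        self.contrast = contrast
        self.fdr_threshold = fdr_threshold
        self.span = span
        self.prior = prior

    def fit(self, X: pd.DataFrame, Y: pd.DataFrame) -> "VoomLimma":
        nonzero = Y.sum(axis=1) > 0
        if not nonzero.all():
            logger.info("dropping %d all-zero genes before DE", int((~nonzero).sum()))
            Y = Y.loc[nonzero]
        if list(X.index) != list(Y.columns):
            Y = Y.loc[:, X.index]
        self.voom_ = voom_weights(Y, X, span=self.span)
        coef, se_u, sigma2, df = weighted_fit(self.voom_.log_cpm, self.voom_.weights, X)
        self.coef_ = coef
        self.se_unscaled_ = se_u
        self.sigma2_ = sigma2
        self.df_resid_ = df
        self.table_ = ebayes_moderate(
            coef, se_u, sigma2, df,
            contrast=self.contrast,
            fdr_threshold=self.fdr_threshold,
            prior=self.prior,
        )
        self.d0_ = self.table_.attrs["d0"]
        self.s0_sq_ = self.table_.attrs["s0_sq"]
        return self


def run_differential_expression(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    fdr_threshold: float = DEFAULT_DEG_FDR,
) -> pd.DataFrame:
    """Thin wrapper returning the DEG table for the condition coefficient."""
    model = VoomLimma(fdr_threshold=fdr_threshold)
    model.fit(design, counts)
    return model.table_
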