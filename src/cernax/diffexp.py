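"""Tumor-vs-normal differential expression via moderated linear models.

Per dataset, the pipeline is the classic two-group microarray workflow: log2
transformation where required, quantile normalization, a probe-wise two-group
linear fit, and empirical-Bayes shrinkage of the residual variances toward a
pooled prior, which lends each feature extra degrees of freedom.  For count
data a voom-style route converts counts to log-CPM with precision weights
from a smoothed mean-variance trend, after which the same moderated fit
applies.

The empirical-Bayes hyperparameters (prior degrees of freedom ``d0`` and
prior variance ``s0^2``) are estimated by moment-matching the scaled-F
distribution of the sample variances on the log scale:

    e_g   = log s_g^2 - digamma(df/2) + log(df/2)
    var(e) - trigamma(df/2) = trigamma(d0/2)          (solved for d0)
    s0^2  = exp( mean(e) + digamma(d0/2) - log(d0/2) )

and the posterior variance of each feature is the df-weighted blend
``(d0*s0^2 + df*s^2) / (d0 + df)``.  The moderated t is the coefficient over
the posterior standard error with ``d0 + df`` degrees of freedom.

Differential calls use the strict thresholds |log2FC| > 1 and BH-adjusted
q < 0.05; a gene sitting exactly on the fold-change boundary is not called.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

LFC_CUT = 1.0
FDR_CUT = 0.05


@dataclass
class DERecord:
    """One feature's differential-expression result."""

    feature: str
    log2fc: float
    t_mod: float
    p: float
    q: float
    direction: str  # up | down | ns


@dataclass
class ModelFit:
    """Per-feature fit plus the empirical-Bayes hyperparameters."""

    coef: pd.Series
    sigma2: pd.Series          # residual variances s^2
    df_residual: float
    d0: float                  # prior degrees of freedom
    s0_squared: float          # prior variance
    posterior_var: pd.Series
    se_factor: pd.Series       # sqrt(1/sum(w_tumor) + 1/sum(w_normal))


# --------------------------------------------------------------------------
# scale handling
# --------------------------------------------------------------------------

def looks_linear(matrix: ExpressionMatrix) -> bool:
    """Heuristic linear-scale detection: max above 50 and right-skewed."""
    arr = matrix.values.to_numpy(float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return False
    return float(arr.max()) > 50 and float(stats.skew(arr)) > 0


def maybe_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Log2-transform a linear-scale matrix as log2(x + 1); pass log2 through.

    Counts are rejected: they belong on the voom path.
    """
    if matrix.scale == "counts":
        raise ValueError("counts input: use voom_transform, not maybe_log2")
    if matrix.scale == "log2":
        return matrix
    arr = matrix.values.to_numpy(float)
    if (arr < 0).any():
        raise ValueError("negative values in linear-scale matrix")
    out = pd.DataFrame(np.log2(arr + 1.0), index=matrix.values.index,
                       columns=matrix.values.columns)
    return matrix.with_values(out, scale="log2")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of column means.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; ties within a column receive the mean of the reference
    values they span.
    """
    if matrix.scale != "log2":
        raise ValueError("quantile_normalize expects a log2-scale matrix")
    df = matrix.values
    if df.shape[1] < 2:
        logger.warning("quantile_normalize: single-sample matrix returned unchanged")
        return matrix
    arr = df.to_numpy(float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average over ties so equal inputs map to equal outputs
        ser = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = ser.to_numpy()
    return matrix.with_values(pd.DataFrame(out, index=df.index, columns=df.columns))


# --------------------------------------------------------------------------
# voom route for counts
# --------------------------------------------------------------------------

def voom_transform(
    counts: ExpressionMatrix, groups: pd.Series | None = None, span: float = 0.5
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Convert counts to log-CPM with precision weights.

    log-CPM = log2((count + 0.5) / (library size + 1) * 1e6).  Weights come
    from a lowess fit (span 0.5) of sqrt residual SD against mean log-CPM,
    inverted to a variance and clipped positive; the trend is extrapolated
    flat beyond the observed range.  All-zero genes are dropped (logged).
    """
    if counts.scale != "counts":
        raise ValueError("voom_transform expects a counts matrix")
    df = counts.values
    nonzero = df.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("voom: excluded %d all-zero genes", n_dropped)
        df = df.loc[nonzero]
    lib = df.sum(axis=0).to_numpy(float)
    if (lib <= 0).any():
        raise ValueError("every sample's library size must be > 0")
    logcpm = np.log2((df.to_numpy(float) + 0.5) / (lib + 1.0) * 1e6)
    logcpm_df = pd.DataFrame(logcpm, index=df.index, columns=df.columns)

    mean_log = logcpm.mean(axis=1)
    if groups is not None:
        labels = pd.Series(groups).reindex(df.columns)
        resid = _group_residuals(logcpm, labels)
        dof = logcpm.shape[1] - labels.nunique()
    else:
        resid = logcpm - mean_log[:, None]
        dof = logcpm.shape[1] - 1
    sd = np.sqrt((resid ** 2).sum(axis=1) / max(dof, 1))
    sqrt_sd = np.sqrt(sd)

    order = np.argsort(mean_log, kind="mergesort")
    fitted = lowess(sqrt_sd[order], mean_log[order], frac=span, return_sorted=True)
    # np.interp is flat beyond the fitted range by construction
    pred_sqrt_sd = np.interp(mean_log, fitted[:, 0], fitted[:, 1])
    pred_sqrt_sd = np.clip(pred_sqrt_sd, 1e-4, None)
    weights_gene = 1.0 / pred_sqrt_sd ** 4
    weights = pd.DataFrame(
        np.repeat(weights_gene[:, None], df.shape[1], axis=1),
        index=df.index, columns=df.columns,
    )
    out = ExpressionMatrix(logcpm_df, scale="log2", platform=counts.platform,
                           meta={**counts.meta, "voom": True})
    return out, weights


def _group_residuals(logcpm: np.ndarray, labels: pd.Series) -> np.ndarray:
    resid = logcpm.astype(float).copy()
    for g in labels.unique():
        mask = (labels == g).to_numpy()
        resid[:, mask] -= logcpm[:, mask].mean(axis=1)[:, None]
    return resid


# --------------------------------------------------------------------------
# empirical-Bayes machinery
# --------------------------------------------------------------------------

def _trigamma_inverse(target: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = target for x > 0 by monotone bisection.

    trigamma is strictly decreasing on (0, inf), from +inf to 0.
    """
    if target <= 0:
        return math.inf
    lo, hi = 1e-8, 1.0
    while special.polygamma(1, hi) > target:
        hi *= 2.0
        if hi > 1e12:
            return hi
    while special.polygamma(1, lo) < target:
        lo /= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, lo):
            break
    return 0.5 * (lo + hi)


def estimate_prior(sigma2: np.ndarray, df_residual: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from observed residual variances.

    Zero variances are excluded from estimation.  If the observed spread of
    log-variances is no larger than the sampling spread, d0 = inf and all
    posterior variances collapse to s0^2.
    """
    s2 = np.asarray(sigma2, float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size == 0:
        return math.inf, float("nan")
    z = np.log(s2)
    e = z - special.digamma(df_residual / 2.0) + math.log(df_residual / 2.0)
    emean = float(e.mean())
    # with an infinite prior df the pooled mean variance is the scale MLE
    if s2.size < 2:
        return math.inf, float(s2.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df_residual / 2.0))
    if evar <= 0:
        return math.inf, float(s2.mean())
    half_d0 = _trigamma_inverse(evar)
    if not math.isfinite(half_d0):
        return math.inf, float(s2.mean())
    d0 = 2.0 * half_d0
    s0_sq = math.exp(emean + special.digamma(half_d0) - math.log(half_d0))
    return d0, s0_sq


def posterior_variance(sigma2, df_residual: float, d0: float, s0_squared: float):
    """Blend observed and prior variances: (d0*s0^2 + df*s^2)/(d0 + df)."""
    s2 = np.asarray(sigma2, float)
    if math.isinf(d0):
        return np.full_like(s2, s0_squared)
    return (d0 * s0_squared + df_residual * s2) / (d0 + df_residual)


# --------------------------------------------------------------------------
# the moderated two-group fit
# --------------------------------------------------------------------------

def fit_and_moderate(
    matrix: ExpressionMatrix,
    groups: pd.Series,
    weights: pd.DataFrame | None = None,
    tumor_label: str = "tumor",
    normal_label: str = "normal",
    lfc_cut: float = LFC_CUT,
    fdr_cut: float = FDR_CUT,
) -> tuple[ModelFit, pd.DataFrame]:
    """Two-group weighted least squares with empirical-Bayes moderation.

    Returns the ModelFit and a DE table (feature, log2fc, t, p, q,
    direction) with the coefficient oriented tumor minus normal.  Features
    whose residual variance is exactly zero receive p = 1.
    """
    labels = pd.Series(groups)
    labels = labels.reindex(matrix.sample_ids)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"samples without group labels: {missing}")
    tmask = (labels == tumor_label).to_numpy()
    nmask = (labels == normal_label).to_numpy()
    if not tmask.any() or not nmask.any():
        raise ValueError(
            f"need both groups {tumor_label!r} and {normal_label!r}; "
            f"got counts {int(tmask.sum())} / {int(nmask.sum())}"
        )
    if int(tmask.sum()) + int(nmask.sum()) != len(labels):
        extra = sorted(set(labels) - {tumor_label, normal_label})
        raise ValueError(f"unknown group labels: {extra}")

    arr = matrix.values.to_numpy(float)
    n = arr.shape[1]
    df_resid = float(n - 2)
    if df_resid <= 0 and weights is None:
        raise ValueError(
            "zero residual degrees of freedom: need at least 3 samples "
            "across the two groups"
        )
    if weights is None:
        w = np.ones_like(arr)
    else:
        w = weights.reindex(index=matrix.values.index, columns=matrix.values.columns).to_numpy(float)
        if np.isnan(w).any() or (w <= 0).any():
            raise ValueError("weights must be positive and cover the matrix")

    wt, wn = w[:, tmask], w[:, nmask]
    xt, xn = arr[:, tmask], arr[:, nmask]
    sw_t, sw_n = wt.sum(axis=1), wn.sum(axis=1)
    mean_t = (wt * xt).sum(axis=1) / sw_t
    mean_n = (wn * xn).sum(axis=1) / sw_n
    coef = mean_t - mean_n
    rss = (wt * (xt - mean_t[:, None]) ** 2).sum(axis=1) + \
          (wn * (xn - mean_n[:, None]) ** 2).sum(axis=1)
    df_resid = max(df_resid, 1.0) if df_resid <= 0 else df_resid
    sigma2 = rss / df_resid
    se_factor = np.sqrt(1.0 / sw_t + 1.0 / sw_n)

    d0, s0_sq = estimate_prior(sigma2, df_resid)
    post = posterior_variance(sigma2, df_resid, d0, s0_sq)

    zero_var = sigma2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = coef / (np.sqrt(post) * se_factor)
    # total df capped at the pooled residual df: moderation cannot borrow
    # more information than all features' residuals together carry
    df_pooled = df_resid * int((sigma2 > 0).sum())
    df_total = min(d0 + df_resid, df_pooled)
    if math.isfinite(df_total) and df_total > 0:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    p = np.where(zero_var | ~np.isfinite(t_mod), 1.0, p)
    t_mod = np.where(zero_var | ~np.isfinite(t_mod), np.nan, t_mod)
    if np.isnan(s0_sq):  # every feature flat: no prior estimable
        p = np.ones_like(p)
    q = bh_adjust(p)

    idx = matrix.values.index
    fit = ModelFit(
        coef=pd.Series(coef, index=idx),
        sigma2=pd.Series(sigma2, index=idx),
        df_residual=df_resid,
        d0=d0,
        s0_squared=s0_sq,
        posterior_var=pd.Series(post, index=idx),
        se_factor=pd.Series(se_factor, index=idx),
    )
    table = pd.DataFrame(
        {"feature": idx, "log2fc": coef, "t": t_mod, "p": p, "q": q}
    ).reset_index(drop=True)
    table["direction"] = _directions(table["log2fc"], table["q"], lfc_cut, fdr_cut)
    return fit, table


def _directions(log2fc, q, lfc_cut: float, fdr_cut: float) -> np.ndarray:
    lfc = np.asarray(log2fc, float)
    qv = np.asarray(q, float)
    out = np.full(lfc.shape, "ns", dtype=object)
    out[(lfc > lfc_cut) & (qv < fdr_cut)] = "up"
    out[(lfc < -lfc_cut) & (qv < fdr_cut)] = "down"
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    table: pd.DataFrame, lfc_cut: float = LFC_CUT, fdr_cut: float = FDR_CUT
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Apply the strict |log2FC| > lfc_cut and q < fdr_cut thresholds.

    Returns (up features, down features, annotated table).  The inequalities
    are strict: a gene at log2FC exactly 1.0 is never called.
    """
    if "q" not in table.columns:
        raise ValueError("DE table lacks a q column; run fit_and_moderate first")
    out = table.copy()
    out["direction"] = _directions(out["log2fc"], out["q"], lfc_cut, fdr_cut)
    up = out.loc[out["direction"] == "up", "feature"].tolist()
    down = out.loc[out["direction"] == "down", "feature"].tolist()
    logger.info("DE calls: %d up, %d down of %d features", len(up), len(down), len(out))
    return up, down, out
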