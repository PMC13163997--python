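"""Median-split survival screening: Kaplan-Meier, log-rank, binary Cox.

For each candidate gene, patients are dichotomized at the median of its
log2 expression (ties go to the low group), overall survival is compared
with the Mantel-Cox log-rank test, and the effect size is a hazard ratio
from a single-binary-covariate Cox proportional-hazards model with Efron
handling of tied event times and a Wald 95% confidence interval
exp(beta +/- 1.96*SE).  Multi-gene screens are labeled exploratory: no
multivariable adjustment is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class CoxResult:
    """Hazard ratio (high vs low group) with Wald CI and log-rank p."""

    hr: float
    ci_low: float
    ci_high: float
    logrank_p: float
    n_high: int
    n_low: int
    beta: float = float("nan")
    se: float = float("nan")
    converged: bool = True


def median_split(expression) -> np.ndarray:
    """Label each patient 'high' (expression > median) or 'low' (ties low)."""
    x = np.asarray(expression, float)
    if x.size < 2:
        raise ValueError("median split needs at least 2 patients")
    med = float(np.median(x))
    if np.all(x == x[0]):
        raise ValueError("all expression values identical: no split possible")
    return np.where(x > med, "high", "low")


def km_estimate(times, events) -> list[tuple[float, float]]:
    """Product-limit survival estimate as (event time, S(t)) pairs."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if (t <= 0).any():
        raise ValueError("times must be strictly positive")
    if e.sum() == 0:
        logger.warning("km_estimate: no events; survival is flat at 1")
        return [(float(tt), 1.0) for tt in np.unique(t)]
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    out = [(float(tt), float(s)) for tt, s in zip(sf.index, sf.iloc[:, 0])]
    return [(tt, s) for tt, s in out if tt > 0]


def logrank_test(groups, times, events) -> tuple[float, float]:
    """Two-group Mantel-Cox log-rank test: (chi-square with 1 df, p)."""
    g = np.asarray(groups)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {list(levels)}")
    if e.sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    m0, m1 = g == levels[0], g == levels[1]
    res = _ll_logrank(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------- Cox model

def cox_partial_loglik(beta: float, time, event, x) -> float:
    """Efron-approximation log partial likelihood for a single covariate."""
    ll, _, _ = _efron_core(beta, np.asarray(time, float),
                           np.asarray(event, int), np.asarray(x, float))
    return ll


def _efron_core(beta: float, time: np.ndarray, event: np.ndarray,
                x: np.ndarray) -> tuple[float, float, float]:
    order = np.argsort(time, kind="mergesort")
    t, d, xv = time[order], event[order], x[order]
    theta = np.exp(beta * xv)
    s0 = np.cumsum(theta[::-1])[::-1]
    s1 = np.cumsum((theta * xv)[::-1])[::-1]
    s2 = np.cumsum((theta * xv * xv)[::-1])[::-1]
    ll = grad = info = 0.0
    i, n = 0, len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        didx = np.arange(i, j)[d[i:j] == 1]
        m = len(didx)
        if m:
            r0, r1, r2 = s0[i], s1[i], s2[i]
            t0 = float(theta[didx].sum())
            t1 = float((theta[didx] * xv[didx]).sum())
            t2 = float((theta[didx] * xv[didx] ** 2).sum())
            ll += beta * float(xv[didx].sum())
            grad += float(xv[didx].sum())
            for k in range(m):
                f = k / m
                a0 = r0 - f * t0
                a1 = r1 - f * t1
                a2 = r2 - f * t2
                ll -= math.log(a0)
                grad -= a1 / a0
                info += a2 / a0 - (a1 / a0) ** 2
        i = j
    return ll, grad, info


def cox_hr_binary(groups, times, events, tol: float = 1e-8,
                  max_iter: int = 60) -> CoxResult:
    """Newton-Raphson Cox fit for a high-vs-low binary covariate.

    Monotone likelihood (e.g. all events in one group) is flagged —
    ``converged=False`` with an infinite confidence interval — rather than
    raised.
    """
    g = np.asarray(groups)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    if e.sum() < 1:
        raise ValueError("Cox fit needs at least one event")
    if "high" in levels and "low" in levels:
        x = (g == "high").astype(float)
    else:
        x = (g == levels[1]).astype(float)
    n_high, n_low = int(x.sum()), int((1 - x).sum())
    _, logrank_p = logrank_test(g, t, e)

    beta = 0.0
    diverged = False
    for _ in range(max_iter):
        ll, grad, info = _efron_core(beta, t, e, x)
        if info <= 0 or not np.isfinite(info):
            diverged = True
            break
        step = grad / info
        beta_new = beta + step
        if abs(beta_new) > 30:
            diverged = True
            beta = beta_new
            break
        if abs(step) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        diverged = True

    if diverged:
        logger.warning("cox_hr_binary: monotone likelihood / non-convergence; "
                       "returning flagged result with infinite CI")
        hr = math.exp(min(max(beta, -30), 30))
        return CoxResult(hr=hr, ci_low=0.0, ci_high=math.inf,
                         logrank_p=logrank_p, n_high=n_high, n_low=n_low,
                         beta=beta, se=math.inf, converged=False)

    _, _, info = _efron_core(beta, t, e, x)
    se = 1.0 / math.sqrt(info)
    return CoxResult(
        hr=math.exp(beta),
        ci_low=math.exp(beta - Z_95 * se),
        ci_high=math.exp(beta + Z_95 * se),
        logrank_p=logrank_p,
        n_high=n_high, n_low=n_low,
        beta=beta, se=se, converged=True,
    )


# ---------------------------------------------------------------- screening

def survival_screen(
    genes: list[str],
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Median-split + log-rank + Cox for each gene; exploratory by design.

    ``expression`` is genes x patients (log2); ``survival`` has columns
    ``time`` and ``event`` indexed by patient.  Genes missing from the
    expression table yield NA rows; the run continues.
    """
    patients = [p for p in survival.index if p in expression.columns]
    surv = survival.loc[patients]
    rows = []
    for gene in genes:
        if gene not in expression.index:
            logger.warning("survival_screen: gene %s missing; NA row", gene)
            rows.append({"gene": gene, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "logrank_p": np.nan,
                         "n_high": 0, "n_low": 0, "significant": False})
            continue
        expr = expression.loc[gene, patients].to_numpy(float)
        labels = median_split(expr)
        res = cox_hr_binary(labels, surv["time"].to_numpy(float),
                            surv["event"].to_numpy(int))
        rows.append({
            "gene": gene, "hr": res.hr, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "logrank_p": res.logrank_p,
            "n_high": res.n_high, "n_low": res.n_low,
            "significant": bool(res.logrank_p < alpha),
        })
    out = pd.DataFrame(rows, columns=["gene", "hr", "ci_low", "ci_high",
                                      "logrank_p", "n_high", "n_low",
                                      "significant"])
    out.attrs["note"] = "exploratory multi-gene screen; no multivariable adjustment"
    return out


def read_survival_tsv(path) -> pd.DataFrame:
    """Read a survival table TSV (patient, time, event[, expression...])."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if not {"time", "event"} <= set(df.columns):
        raise ValueError("survival table needs 'time' and 'event' columns")
    return df
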