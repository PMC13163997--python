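"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately coded in the most literal way possible
(explicit loops, closed forms, grid searches) and shares no code with the
package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special
from scipy.optimize import brentq


# ------------------------------------------------------- moderated t-statistic

def moderated_t_reference(X: np.ndarray, tumor_mask: np.ndarray):
    """Literal per-feature two-group fit + moment-matching moderation."""
    n = X.shape[1]
    df = n - 2
    coefs, s2s, ses = [], [], []
    nt, nn = int(tumor_mask.sum()), int((~tumor_mask).sum())
    for row in X:
        xt, xn = row[tumor_mask], row[~tumor_mask]
        coef = xt.mean() - xn.mean()
        rss = ((xt - xt.mean()) ** 2).sum() + ((xn - xn.mean()) ** 2).sum()
        coefs.append(coef)
        s2s.append(rss / df)
        ses.append(math.sqrt(1.0 / nt + 1.0 / nn))
    s2 = np.array(s2s)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        half_d0 = brentq(lambda x: special.polygamma(1, x) - evar, 1e-8, 1e8,
                         xtol=1e-12)
        d0 = 2.0 * half_d0
        s0 = math.exp(emean + special.digamma(half_d0) - math.log(half_d0))
        post = (d0 * s0 + df * s2) / (d0 + df)
    else:
        d0 = math.inf
        s0 = s2.mean()  # pooled variance: the scale MLE at infinite prior df
        post = np.full_like(s2, s0)
    t = np.array(coefs) / (np.sqrt(post) * np.array(ses))
    return t, d0, s0


# ----------------------------------------------------------------- Cox model

def cox_loglik_reference(beta: float, time, event, x) -> float:
    """Efron partial log-likelihood via explicit risk-set loops."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        D = np.where((time == t) & (event == 1))[0]
        R = np.where(time >= t)[0]
        m = len(D)
        ll += beta * x[D].sum()
        sR = np.exp(beta * x[R]).sum()
        sD = np.exp(beta * x[D]).sum()
        for k in range(m):
            ll -= math.log(sR - (k / m) * sD)
    return ll


def cox_beta_gridsearch(time, event, x, lo=-6.0, hi=6.0) -> float:
    """Two-stage grid maximization of the reference partial likelihood."""
    coarse = np.arange(lo, hi + 1e-9, 0.01)
    lls = [cox_loglik_reference(b, time, event, x) for b in coarse]
    best = coarse[int(np.argmax(lls))]
    fine = np.arange(best - 0.01, best + 0.01 + 1e-12, 1e-4)
    lls = [cox_loglik_reference(b, time, event, x) for b in fine]
    return float(fine[int(np.argmax(lls))])


# ------------------------------------------------------------- DeLong variance

def delong_variance_reference(pos, neg) -> float:
    """Structural-component variance from the full placement matrix."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    m, n = len(pos), len(neg)
    psi = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            if pos[i] > neg[j]:
                psi[i, j] = 1.0
            elif pos[i] == neg[j]:
                psi[i, j] = 0.5
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


# --------------------------------------------------------------- hypergeometric

def hypergeom_upper_tail_reference(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] as an explicit sum of binomial-coefficient ratios."""
    total = 0
    denom = math.comb(N, n)
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


# ----------------------------------------------------------- triplet assembly

def triplets_reference(lnc_mir_pairs, mir_mrna_pairs, directions):
    """Brute-force enumeration of all sign-consistent combinations."""
    lset = set(lnc_mir_pairs)
    mset = set(mir_mrna_pairs)
    lncs = {l for l, _ in lnc_mir_pairs}
    mirs = {m for _, m in lnc_mir_pairs} | {m for m, _ in mir_mrna_pairs}
    mrnas = {g for _, g in mir_mrna_pairs}
    out = set()
    for l in lncs:
        for m in mirs:
            for g in mrnas:
                if (l, m) in lset and (m, g) in mset \
                        and directions[l] == directions[g] != directions[m]:
                    out.add((l, m, g))
    return out


# ------------------------------------------------------ predictor intersection

def intersection_reference(pairs_a, pairs_b):
    return set(pairs_a) & set(pairs_b)
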