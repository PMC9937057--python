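"""Independent oracles used by the test suite.

These deliberately re-implement, in plain loops, the procedures the library
computes through its optimized paths: a from-scratch per-fold two-stage LOO
(checking the nesting, restandardization and aggregation), exhaustive
permutation enumeration for the Mann-Whitney test, and the textbook
rank-sum formula for Kruskal-Wallis. The LOO oracle reuses the library's
`lasso_select` primitive (the coordinate-descent solver is itself checked
against scikit-learn elsewhere) but owns every other step.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from climblearn.predict import lasso_select


def naive_fit_predict(Xtr, ytr, x_new, lam, max_sel, inner=False):
    """One two-stage fit, written out longhand. Returns (yhat, mask).

    ``inner=True`` reproduces the refit semantics used when scoring the
    penalty grid: normal equations with a vanishing ridge, under which a
    numerically singular fold disqualifies itself through an exploding
    prediction (distinct least-squares algorithms legitimately diverge on
    such folds, so the oracle must pin the same convention; the final
    refits use plain least squares in both implementations).
    """
    Xtr = np.asarray(Xtr, float)
    ytr = np.asarray(ytr, float)
    n, p = Xtr.shape
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (Xtr - mu) / sd_safe
    Xs[:, sd == 0] = 0.0
    _, beta = lasso_select(Xs, ytr, lam)
    support = [j for j in range(p) if beta[j] != 0.0]
    support.sort(key=lambda j: (-abs(beta[j]), j))
    support = sorted(support[:max_sel])
    A = np.column_stack([np.ones(n)] + [Xtr[:, j] for j in support])
    if inner:
        ata = A.T @ A
        eps = 1e-12 * (1.0 + np.trace(ata))
        coef = np.linalg.solve(ata + eps * np.eye(len(ata)), A.T @ ytr)
    else:
        coef = np.linalg.lstsq(A, ytr, rcond=None)[0]
    yhat = coef[0] + sum(coef[1 + k] * x_new[j] for k, j in enumerate(support))
    mask = np.zeros(p, dtype=bool)
    mask[support] = True
    return float(yhat), mask


def naive_lambda_grid(Xtr, ytr, n_lambdas=50, min_ratio=1e-3):
    Xtr = np.asarray(Xtr, float)
    ytr = np.asarray(ytr, float)
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (Xtr - mu) / sd_safe
    Xs[:, sd == 0] = 0.0
    yc = ytr - ytr.mean()
    lam_max = max(float(np.max(np.abs(Xs.T @ yc)) / len(ytr)), 1e-12)
    if n_lambdas == 1:
        return np.array([lam_max])
    return np.geomspace(lam_max * min_ratio, lam_max, n_lambdas)


def naive_select_lambda(Xtr, ytr, n_lambdas=50, min_ratio=1e-3):
    grid = naive_lambda_grid(Xtr, ytr, n_lambdas, min_ratio)
    m = len(ytr)
    sse = np.zeros(len(grid))
    for l, lam in enumerate(grid):
        for i in range(m):
            keep = [a for a in range(m) if a != i]
            yhat, _ = naive_fit_predict(
                Xtr[keep], ytr[keep], Xtr[i], lam, max_sel=(m - 1) - 2, inner=True
            )
            sse[l] += (yhat - ytr[i]) ** 2
    best = np.flatnonzero(sse == sse.min())[-1]
    return float(grid[best])


def naive_loo_two_stage(X, y, n_lambdas=50, min_ratio=1e-3):
    """From-scratch nested LOO; returns (errors, masks, lambdas)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    errors = np.zeros(n)
    masks = []
    lams = []
    for i in range(n):
        keep = [a for a in range(n) if a != i]
        Xtr, ytr = X[keep], y[keep]
        lam = naive_select_lambda(Xtr, ytr, n_lambdas, min_ratio)
        yhat, mask = naive_fit_predict(Xtr, ytr, X[i], lam, max_sel=len(ytr) - 2)
        errors[i] = (yhat - y[i]) ** 2
        masks.append(mask)
        lams.append(lam)
    return errors, masks, lams


def mw_u_statistic(a, b):
    """U of sample a over b with half-credit for ties."""
    u = 0.0
    for x in a:
        for z in b:
            if x < z:
                u += 1.0
            elif x == z:
                u += 0.5
    return u


def mw_exact_p_enumeration(a, b):
    """Exact two-sided p by enumerating every group assignment of the pooled
    values (tie-free samples only). Returns (U_min_convention, p)."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)
    u_obs = mw_u_statistic(a, b)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(mw_u_statistic(ga, gb))
    us = np.array(us)
    p_low = float(np.mean(us <= u_obs))
    p_high = float(np.mean(us >= u_obs))
    p = min(1.0, 2.0 * min(p_low, p_high))
    n2 = len(b)
    return min(u_obs, n1 * n2 - u_obs), p


def kw_h_by_hand(samples):
    """Kruskal-Wallis H from the rank-sum formula (no ties expected)."""
    pooled = np.concatenate([np.asarray(s, float) for s in samples])
    order = pooled.argsort()
    ranks = np.empty_like(pooled)
    ranks[order] = np.arange(1, len(pooled) + 1)
    n_total = len(pooled)
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start : start + len(s)]
        h += r.sum() ** 2 / len(s)
        start += len(s)
    return 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
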