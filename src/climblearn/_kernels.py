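"""Compiled hot-path kernels.

Everything here is called millions of times inside cohort-replication
simulations, so it is written as plain loops and jitted with numba:
profiled exponential least squares, coordinate-descent lasso, small OLS
solves, and the nested leave-one-out lambda search of the two-stage model.
The public modules (`curves`, `predict`) wrap these with validation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_GOLDEN = 0.6180339887498949


@njit(cache=True)
def profile_sse(tt, vv, b):
    """SSE of f(t)=a+c*exp(-b*t) profiled over (a, c) at fixed rate b.

    Returns (sse, a, c). Uses the centered linear solve so tiny rates do not
    lose precision to cancellation. A rate that leaves the regressor constant
    degenerates to the best constant model (c = 0).
    """
    n = tt.shape[0]
    w = np.exp(-b * tt)
    wbar = 0.0
    vbar = 0.0
    for i in range(n):
        wbar += w[i]
        vbar += vv[i]
    wbar /= n
    vbar /= n
    sww = 0.0
    swv = 0.0
    for i in range(n):
        wc = w[i] - wbar
        sww += wc * wc
        swv += wc * (vv[i] - vbar)
    if sww <= 0.0:
        sse = 0.0
        for i in range(n):
            d = vv[i] - vbar
            sse += d * d
        return sse, vbar, 0.0
    c = swv / sww
    a = vbar - c * wbar
    sse = 0.0
    for i in range(n):
        d = a + c * w[i] - vv[i]
        sse += d * d
    return sse, a, c


@njit(cache=True)
def fit_exp(tt, vv, b_grid, tol):
    """Exponential fit min_{a,b,c} sum (a + c*exp(-b*t) - v)^2 with b >= 0.

    Coarse search over `b_grid` (which must be sorted ascending and positive)
    plus the constant model b=0, then golden-section refinement around the
    best bracket. Returns (a, b, c, sse).
    """
    n = vv.shape[0]
    vbar = 0.0
    for i in range(n):
        vbar += vv[i]
    vbar /= n
    sse0 = 0.0
    for i in range(n):
        d = vv[i] - vbar
        sse0 += d * d

    best_sse = sse0
    best_a = vbar
    best_b = 0.0
    best_c = 0.0
    best_idx = -1
    for k in range(b_grid.shape[0]):
        sse, a, c = profile_sse(tt, vv, b_grid[k])
        if sse < best_sse:
            best_sse = sse
            best_a = a
            best_b = b_grid[k]
            best_c = c
            best_idx = k

    if best_idx < 0:
        return best_a, best_b, best_c, best_sse

    lo = 0.0 if best_idx == 0 else b_grid[best_idx - 1]
    if best_idx == b_grid.shape[0] - 1:
        hi = b_grid[best_idx] * 4.0
    else:
        hi = b_grid[best_idx + 1]

    # golden-section refinement of the profiled objective on [lo, hi]
    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1, a1, c1 = profile_sse(tt, vv, x1)
    f2, a2, c2 = profile_sse(tt, vv, x2)
    for _ in range(200):
        if hi - lo <= tol * (1.0 + hi):
            break
        if f1 <= f2:
            hi = x2
            x2 = x1
            f2 = f1
            x1 = hi - _GOLDEN * (hi - lo)
            f1, a1, c1 = profile_sse(tt, vv, x1)
        else:
            lo = x1
            x1 = x2
            f1 = f2
            x2 = lo + _GOLDEN * (hi - lo)
            f2, a2, c2 = profile_sse(tt, vv, x2)
    if f1 <= f2:
        fb, ab, cb, bb = f1, a1, c1, x1
    else:
        fb, ab, cb, bb = f2, a2, c2, x2
    if fb < best_sse:
        best_sse = fb
        best_a = ab
        best_b = bb
        best_c = cb
    return best_a, best_b, best_c, best_sse


@njit(cache=True)
def _cd_sweeps(G, r, lam, beta, tol, max_iter):
    """Cyclic coordinate-descent sweeps on beta in place; see cd_lasso_warm."""
    p = r.shape[0]
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            rho = r[j] + gjj * beta[j]
            for k in range(p):
                rho -= G[j, k] * beta[k]
            if rho > lam:
                bn = (rho - lam) / gjj
            elif rho < -lam:
                bn = (rho + lam) / gjj
            else:
                bn = 0.0
            d = abs(bn - beta[j])
            if d > delta:
                delta = d
            beta[j] = bn
        if delta < tol:
            break
    return beta


@njit(cache=True)
def _gauss_solve(A, b):
    """Partial-pivot Gaussian elimination; returns (x, failed_col).

    failed_col is -1 on success, else the index of the column whose pivot
    vanished (a column linearly dependent on the preceding ones).
    """
    k = b.shape[0]
    M = A.copy()
    x = b.copy()
    scale = 0.0
    for col in range(k):
        if abs(A[col, col]) > scale:
            scale = abs(A[col, col])
    for col in range(k):
        piv = col
        best = abs(M[col, col])
        for row in range(col + 1, k):
            if abs(M[row, col]) > best:
                best = abs(M[row, col])
                piv = row
        if best <= 1e-13 * scale:
            return x, col
        if piv != col:
            for j in range(k):
                tmp = M[col, j]
                M[col, j] = M[piv, j]
                M[piv, j] = tmp
            tmp = x[col]
            x[col] = x[piv]
            x[piv] = tmp
        for row in range(col + 1, k):
            f = M[row, col] / M[col, col]
            if f != 0.0:
                for j in range(col, k):
                    M[row, j] -= f * M[col, j]
                x[row] -= f * x[col]
    for col in range(k - 1, -1, -1):
        s = x[col]
        for j in range(col + 1, k):
            s -= M[col, j] * x[j]
        x[col] = s / M[col, col]
    return x, -1


@njit(cache=True)
def cd_lasso_warm(G, r, lam, beta, tol, max_iter):
    """Lasso solve for min_b 1/(2n)||y-Xb||^2 + lam*||b||_1, warm-started.

    G = X'X/n and r = X'y/n for column-standardized X and centered y;
    `beta` is updated in place. A few coordinate-descent sweeps propose an
    active set; an active-set refinement loop then solves the restricted
    KKT system exactly, removing wrong-signed variables and adding the
    most-violating inactive one until the full KKT conditions hold. The
    returned point is the exact (machine-precision) lasso solution, which
    is a.s. unique for continuous data, so the result does not depend on
    the warm start. Plain coordinate descent to `tol` is the rare
    fallback when the refinement cycles (degenerate designs).
    """
    p = r.shape[0]
    coarse = tol if tol > 1e-6 else 1e-6
    cap = max_iter if max_iter < 2000 else 2000
    _cd_sweeps(G, r, lam, beta, coarse, cap)
    kkt_tol = 1e-10 * (1.0 + lam)

    active = np.zeros(p, dtype=np.bool_)
    signs = np.zeros(p)
    for j in range(p):
        if beta[j] != 0.0:
            active[j] = True
            signs[j] = 1.0 if beta[j] > 0.0 else -1.0

    for _ in range(120):
        k = 0
        for j in range(p):
            if active[j]:
                k += 1
        if k == 0:
            worst = -1.0
            wj = -1
            for j in range(p):
                if abs(r[j]) > worst:
                    worst = abs(r[j])
                    wj = j
            if worst <= lam + kkt_tol:
                for j in range(p):
                    beta[j] = 0.0
                return beta
            active[wj] = True
            signs[wj] = 1.0 if r[wj] > 0.0 else -1.0
            continue

        idx = np.empty(k, dtype=np.int64)
        c = 0
        for j in range(p):
            if active[j]:
                idx[c] = j
                c += 1
        A = np.empty((k, k))
        b = np.empty(k)
        for a in range(k):
            for bb in range(k):
                A[a, bb] = G[idx[a], idx[bb]]
            b[a] = r[idx[a]] - lam * signs[idx[a]]
        x, failed = _gauss_solve(A, b)
        if failed >= 0:
            # drop the active column that proved linearly dependent
            active[idx[failed]] = False
            continue
        # remove the worst wrong-signed variable, if any
        worst = 0.0
        wa = -1
        for a in range(k):
            v = x[a] * signs[idx[a]]
            if v <= 0.0 and (wa < 0 or v < worst):
                worst = v
                wa = a
        if wa >= 0:
            active[idx[wa]] = False
            continue
        # inactive KKT: add the most violating coordinate, if any
        worst = lam + kkt_tol
        wj = -1
        wg = 0.0
        for j in range(p):
            if active[j]:
                continue
            g = r[j]
            for a in range(k):
                g -= G[j, idx[a]] * x[a]
            if abs(g) > worst:
                worst = abs(g)
                wj = j
                wg = g
        if wj < 0:
            for j in range(p):
                beta[j] = 0.0
            for a in range(k):
                beta[idx[a]] = x[a]
            return beta
        active[wj] = True
        signs[wj] = 1.0 if wg > 0.0 else -1.0

    # refinement cycled (degenerate design): deterministic from-zeros descent
    # so the result cannot depend on the warm start
    for j in range(p):
        beta[j] = 0.0
    _cd_sweeps(G, r, lam, beta, tol, max_iter if max_iter < 200000 else 200000)
    return beta


@njit(cache=True)
def cd_lasso(G, r, lam, tol, max_iter):
    """Lasso solve from the zero vector."""
    beta = np.zeros(r.shape[0])
    return cd_lasso_warm(G, r, lam, beta, tol, max_iter)


@njit(cache=True)
def standardize_cols(X):
    """Column-wise z-scoring with population SD; constant columns map to 0."""
    n, p = X.shape
    mu = np.empty(p)
    sd = np.empty(p)
    Xs = np.empty_like(X)
    for j in range(p):
        m = 0.0
        for i in range(n):
            m += X[i, j]
        m /= n
        mu[j] = m
        s = 0.0
        for i in range(n):
            d = X[i, j] - m
            s += d * d
        s = np.sqrt(s / n)
        sd[j] = s
        if s > 0.0:
            for i in range(n):
                Xs[i, j] = (X[i, j] - m) / s
        else:
            for i in range(n):
                Xs[i, j] = 0.0
    return Xs, mu, sd


@njit(cache=True)
def cap_mask(beta, max_sel):
    """Boolean support of beta capped at max_sel entries.

    Kept entries are those with the largest |beta|; ties resolve to the
    lower column index (the scan below visits indices in order and only
    replaces on a strictly larger magnitude).
    """
    p = beta.shape[0]
    sel = np.zeros(p, dtype=np.bool_)
    if max_sel <= 0:
        return sel
    nkeep = 0
    for j in range(p):
        if beta[j] != 0.0:
            nkeep += 1
    if nkeep > max_sel:
        nkeep = max_sel
    for _ in range(nkeep):
        best = -1.0
        bj = -1
        for j in range(p):
            if beta[j] != 0.0 and not sel[j]:
                ab = abs(beta[j])
                if ab > best:
                    best = ab
                    bj = j
        sel[bj] = True
    return sel


@njit(cache=True)
def ols_solve_predict(Xtr, ytr, xte, sel):
    """Intercept OLS on the selected raw columns via normal equations.

    A vanishing-ridge term keeps degenerate (collinear-selection) inner
    folds from crashing; their inflated error simply disqualifies that
    penalty. Returns the prediction for the single row `xte`.
    """
    n = Xtr.shape[0]
    p = Xtr.shape[1]
    k = 0
    for j in range(p):
        if sel[j]:
            k += 1
    cols = np.empty(k, dtype=np.int64)
    c = 0
    for j in range(p):
        if sel[j]:
            cols[c] = j
            c += 1
    ata = np.zeros((k + 1, k + 1))
    atb = np.zeros(k + 1)
    ata[0, 0] = n
    for i in range(n):
        atb[0] += ytr[i]
    for a in range(k):
        ja = cols[a]
        s = 0.0
        sb = 0.0
        for i in range(n):
            s += Xtr[i, ja]
            sb += Xtr[i, ja] * ytr[i]
        ata[0, a + 1] = s
        ata[a + 1, 0] = s
        atb[a + 1] = sb
        for b in range(a, k):
            jb = cols[b]
            q = 0.0
            for i in range(n):
                q += Xtr[i, ja] * Xtr[i, jb]
            ata[a + 1, b + 1] = q
            ata[b + 1, a + 1] = q
    tr = 0.0
    for a in range(k + 1):
        tr += ata[a, a]
    eps = 1e-12 * (1.0 + tr)
    for a in range(k + 1):
        ata[a, a] += eps
    coef = np.linalg.solve(ata, atb)
    v = coef[0]
    for a in range(k):
        v += coef[a + 1] * xte[cols[a]]
    return v


@njit(cache=True)
def inner_loo_sse(X, y, lams, cd_tol, cd_max_iter):
    """Leave-one-out SSE of the two-stage predictor for every lambda.

    For each held-in fold the design is restandardized once, then every
    lambda is lasso-selected (coordinate descent from zeros), capped at
    (fold size - 2), OLS-refitted and evaluated on the held-out sample.
    Returns the SSE vector over `lams`.
    """
    m, p = X.shape
    L = lams.shape[0]
    sse = np.zeros(L)
    Xi = np.empty((m - 1, p))
    yi = np.empty(m - 1)
    xte = np.empty(p)
    max_sel = (m - 1) - 2
    for i in range(m):
        r = 0
        for a in range(m):
            if a == i:
                continue
            for j in range(p):
                Xi[r, j] = X[a, j]
            yi[r] = y[a]
            r += 1
        for j in range(p):
            xte[j] = X[i, j]
        Xs, mu, sd = standardize_cols(Xi)
        nfold = m - 1
        ybar = 0.0
        for a in range(nfold):
            ybar += yi[a]
        ybar /= nfold
        yc = yi - ybar
        G = (Xs.T @ Xs) / nfold
        rv = (Xs.T @ yc) / nfold
        # pathwise: descend the (ascending) grid warm-starting each solve
        beta = np.zeros(p)
        for l in range(L - 1, -1, -1):
            cd_lasso_warm(G, rv, lams[l], beta, cd_tol, cd_max_iter)
            sel = cap_mask(beta, max_sel)
            pred = ols_solve_predict(Xi, yi, xte, sel)
            d = pred - y[i]
            sse[l] += d * d
    return sse
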