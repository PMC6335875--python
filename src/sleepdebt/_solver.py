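"""Coordinate-descent kernels for elastic-net penalized (weighted) least
squares.  These kernels operate on standardized design matrices; all
standardization and back-transformation lives in :mod:`sleepdebt.penalized`.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def soft_threshold(z, gamma):
    """sign(z) * max(|z| - gamma, 0)."""
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


@njit(cache=True)
def _objective(r, w, beta, l1, l2, n):
    q = 0.0
    for i in range(r.shape[0]):
        q += w[i] * r[i] * r[i]
    q *= 0.5 / n
    la = 0.0
    lb = 0.0
    for j in range(beta.shape[0]):
        la += abs(beta[j])
        lb += beta[j] * beta[j]
    return q + l1 * la + 0.5 * l2 * lb


@njit(cache=True)
def _sweep(X, w, r, beta, beta0, xv, l1, l2, wsum, fit_intercept, active_only):
    """One pass of cyclic coordinate updates; returns max |coef change|."""
    n, p = X.shape
    dmax = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        g = 0.0
        for i in range(n):
            g += w[i] * X[i, j] * r[i]
        g = g / n + xv[j] * bj
        denom = xv[j] + l2
        if denom <= 0.0:
            new = 0.0
        else:
            new = soft_threshold(g, l1) / denom
        d = new - bj
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            beta[j] = new
            ad = abs(d)
            if ad > dmax:
                dmax = ad
    if fit_intercept and wsum > 0.0:
        g = 0.0
        for i in range(n):
            g += w[i] * r[i]
        d = g / wsum
        if d != 0.0:
            beta0[0] += d
            for i in range(n):
                r[i] -= d
            ad = abs(d)
            if ad > dmax:
                dmax = ad
    return dmax


@njit(cache=True)
def _solve_at(X, w, r, beta, beta0, xv, l1, l2, wsum, tol, max_sweeps, fit_intercept):
    """Iterate sweeps (full, then active-set) until max coef change < tol."""
    sweeps = 0
    converged = False
    while sweeps < max_sweeps:
        d = _sweep(X, w, r, beta, beta0, xv, l1, l2, wsum, fit_intercept, False)
        sweeps += 1
        if d < tol:
            converged = True
            break
        while sweeps < max_sweeps:
            d = _sweep(X, w, r, beta, beta0, xv, l1, l2, wsum, fit_intercept, True)
            sweeps += 1
            if d < tol:
                break
    return sweeps, converged


@njit(cache=True)
def enet_path_gaussian(Xs, yc, lambdas, alpha, tol, max_sweeps):
    """Warm-started elastic-net path for the gaussian family.

    ``Xs`` must be column-centered (standardized) and ``yc`` mean-centered, so
    the intercept of the centered problem is identically zero.  Returns the
    (p, L) coefficient matrix on the standardized scale.
    """
    n, p = Xs.shape
    L = lambdas.shape[0]
    B = np.zeros((p, L))
    beta = np.zeros(p)
    r = yc.copy()
    w = np.ones(n)
    xv = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Xs[i, j] * Xs[i, j]
        xv[j] = s / n
    b0 = np.zeros(1)
    total = 0
    for li in range(L):
        lam = lambdas[li]
        sweeps, _ = _solve_at(
            Xs, w, r, beta, b0, xv, lam * alpha, lam * (1.0 - alpha), float(n),
            tol, max_sweeps, False,
        )
        total += sweeps
        for j in range(p):
            B[j, li] = beta[j]
    return B, total


@njit(cache=True)
def enet_path_binomial(Xs, y, lambdas, alpha, tol, max_sweeps, irls_max, prob_clip):
    """Warm-started elastic-net path for the binomial family via penalized
    IRLS around coordinate descent.  Returns standardized-scale coefficients
    (p, L) and intercepts (L,).

    When the in-sample deviance is >99% explained (near-separation, common
    for n << p at small lambda) the remaining path entries reuse the current
    solution: the fit cannot meaningfully improve and unbounded coefficient
    growth only destabilizes the weights.
    """
    n, p = Xs.shape
    L = lambdas.shape[0]
    B = np.zeros((p, L))
    b0s = np.zeros(L)
    beta = np.zeros(p)
    pbar = y.mean()
    b0 = np.zeros(1)
    b0[0] = np.log(pbar / (1.0 - pbar))
    dev0 = 0.0
    for i in range(n):
        dev0 -= 2.0 * (y[i] * np.log(pbar) + (1.0 - y[i]) * np.log(1.0 - pbar))
    w = np.empty(n)
    z = np.empty(n)
    total = 0
    saturated = False
    for li in range(L):
        if saturated:
            for j in range(p):
                B[j, li] = beta[j]
            b0s[li] = b0[0]
            continue
        lam = lambdas[li]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for _ in range(irls_max):
            eta = b0[0] + Xs.dot(beta)
            dmax_irls = 0.0
            wsum = 0.0
            for i in range(n):
                pr = 1.0 / (1.0 + np.exp(-eta[i]))
                if pr < prob_clip:
                    pr = prob_clip
                elif pr > 1.0 - prob_clip:
                    pr = 1.0 - prob_clip
                w[i] = pr * (1.0 - pr)
                z[i] = eta[i] + (y[i] - pr) / w[i]
                wsum += w[i]
            xv = np.empty(p)
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * Xs[i, j] * Xs[i, j]
                xv[j] = s / n
            beta_old = beta.copy()
            b0_old = b0[0]
            r = np.empty(n)
            fit0 = Xs.dot(beta)
            for i in range(n):
                r[i] = z[i] - b0[0] - fit0[i]
            sweeps, _ = _solve_at(Xs, w, r, beta, b0, xv, l1, l2, wsum,
                                  tol, max_sweeps, True)
            total += sweeps
            for j in range(p):
                d = abs(beta[j] - beta_old[j])
                if d > dmax_irls:
                    dmax_irls = d
            d = abs(b0[0] - b0_old)
            if d > dmax_irls:
                dmax_irls = d
            if dmax_irls < tol * 10.0:
                break
        for j in range(p):
            B[j, li] = beta[j]
        b0s[li] = b0[0]
        eta = b0[0] + Xs.dot(beta)
        dev = 0.0
        for i in range(n):
            pr = 1.0 / (1.0 + np.exp(-eta[i]))
            if pr < prob_clip:
                pr = prob_clip
            elif pr > 1.0 - prob_clip:
                pr = 1.0 - prob_clip
            dev -= 2.0 * (y[i] * np.log(pr) + (1.0 - y[i]) * np.log(1.0 - pr))
        if dev < 0.01 * dev0:
            saturated = True
    return B, b0s, total


@njit(cache=True)
def cd_solve(X, w, z, beta, beta0, l1, l2, tol, max_sweeps, fit_intercept, obj_hist):
    """Solve min_{b0,b} (1/2n) sum_i w_i (z_i - b0 - x_i.b)^2
    + l1 ||b||_1 + (l2/2) ||b||_2^2 by cyclic coordinate descent with an
    active-set strategy.  ``beta``/``beta0`` are updated in place (warm
    starts).  Objective values after each sweep are written into ``obj_hist``.
    Returns (sweeps, converged flag, number of recorded objective values).
    """
    n, p = X.shape
    r = z - beta0[0] - X.dot(beta)
    wsum = 0.0
    for i in range(n):
        wsum += w[i]
    xv = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        xv[j] = s / n
    sweeps = 0
    nobj = 0
    converged = False
    cap = obj_hist.shape[0]
    while sweeps < max_sweeps:
        d = _sweep(X, w, r, beta, beta0, xv, l1, l2, wsum, fit_intercept, False)
        sweeps += 1
        if nobj < cap:
            obj_hist[nobj] = _objective(r, w, beta, l1, l2, n)
            nobj += 1
        if d < tol:
            converged = True
            break
        while sweeps < max_sweeps:
            d = _sweep(X, w, r, beta, beta0, xv, l1, l2, wsum, fit_intercept, True)
            sweeps += 1
            if nobj < cap:
                obj_hist[nobj] = _objective(r, w, beta, l1, l2, n)
                nobj += 1
            if d < tol:
                break
    return sweeps, converged, nobj
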