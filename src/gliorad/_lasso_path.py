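"""Coordinate-descent solver for the L1-penalized logistic regression path.

Implements the standard penalized-IRLS scheme: an outer loop forms the
quadratic (weighted least squares) approximation to the binomial
log-likelihood at the current linear predictor, and an inner cyclic
coordinate-descent loop solves the penalized weighted problem by
soft-thresholding; the path is solved for a descending penalty grid with
warm starts.  The objective is

    (1/n) * sum_i [log(1 + exp(eta_i)) - y_i eta_i] + lambda * ||beta||_1

with an unpenalized intercept, i.e. the same parameterization as the
reference R implementation, so ``lambda`` values are directly comparable.
Predictors are expected to be standardized by the caller.

Compiled with numba; agreement with an independent solver is part of the
test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_P_CLAMP = 1e-5


@njit(cache=True, fastmath=True)
def _sweep(XT, w, s, eta, beta, b0, lam, xsq, n, wsum, js):
    """One coordinate-descent pass over the features in ``js`` plus the
    intercept.  ``s`` is the maintained weighted working residual
    s_i = w_i (z_i - eta_i); returns (max abs coefficient change, b0)."""
    dmax = 0.0
    for jj in range(js.shape[0]):
        j = js[jj]
        dot = 0.0
        for i in range(n):
            dot += XT[j, i] * s[i]
        rho = xsq[j] * beta[j] + dot / n
        if rho > lam:
            newb = (rho - lam) / xsq[j]
        elif rho < -lam:
            newb = (rho + lam) / xsq[j]
        else:
            newb = 0.0
        d = newb - beta[j]
        if d != 0.0:
            beta[j] = newb
            for i in range(n):
                eta[i] += XT[j, i] * d
                s[i] -= w[i] * XT[j, i] * d
            if abs(d) > dmax:
                dmax = abs(d)
    num = 0.0
    for i in range(n):
        num += s[i]
    d0 = num / wsum
    if d0 != 0.0:
        b0 += d0
        for i in range(n):
            eta[i] += d0
            s[i] -= w[i] * d0
        if abs(d0) > dmax:
            dmax = abs(d0)
    return dmax, b0


@njit(cache=True, fastmath=True)
def _gradient(XT, y, eta, g):
    """g_j = (1/n) sum_i x_ij (sigmoid(eta_i) - y_i) for all features."""
    p, n = XT.shape
    r = np.empty(n)
    for i in range(n):
        r[i] = 1.0 / (1.0 + np.exp(-eta[i])) - y[i]
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += XT[j, i] * r[i]
        g[j] = s / n


@njit(cache=True, fastmath=True)
def _logistic_cd_path(
    XT: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float,
    max_outer: int,
    max_inner: int,
    dfmax: int,
):
    p, n = XT.shape
    nl = lambdas.shape[0]
    coefs = np.zeros((nl, p))
    intercepts = np.zeros(nl)
    ybar = y.mean()
    beta = np.zeros(p)
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    dev_null = 0.0
    for i in range(n):
        dev_null += np.log(1.0 + np.exp(b0)) - y[i] * b0
    dev_null = 2.0 * dev_null / n
    xsq = np.empty(p)
    w = np.empty(n)
    z = np.empty(n)
    sres = np.empty(n)
    g = np.empty(p)
    in_set = np.zeros(p, dtype=np.bool_)
    lam_prev = lambdas[0]
    for li in range(nl):
        lam = lambdas[li]
        # sequential strong rule: screen to features whose gradient at the
        # previous solution is near the new penalty, plus the active set;
        # a KKT sweep over all features afterwards restores exactness
        _gradient(XT, y, eta, g)
        thresh = 2.0 * lam - lam_prev if li > 0 else lam * (1.0 - 1e-12)
        for j in range(p):
            in_set[j] = beta[j] != 0.0 or abs(g[j]) >= thresh
        for _kkt_round in range(20):
            ever = in_set.copy()
            screened = np.flatnonzero(in_set)
            for _outer in range(max_outer):
                # quadratic approximation at the current linear predictor
                wsum = 0.0
                for i in range(n):
                    pr = 1.0 / (1.0 + np.exp(-eta[i]))
                    if pr < _P_CLAMP:
                        pr = _P_CLAMP
                    elif pr > 1.0 - _P_CLAMP:
                        pr = 1.0 - _P_CLAMP
                    wi = pr * (1.0 - pr)
                    w[i] = wi
                    z[i] = eta[i] + (y[i] - pr) / wi
                    sres[i] = y[i] - pr  # w * (z - eta)
                    wsum += wi
                for jj in range(screened.shape[0]):
                    j = screened[jj]
                    s = 0.0
                    for i in range(n):
                        s += w[i] * XT[j, i] * XT[j, i]
                    xsq[j] = s / n
                outer_change = 0.0
                # alternate screened passes with active-set passes until a
                # screened pass no longer moves any coefficient
                for _cycle in range(max_inner):
                    dmax, b0 = _sweep(XT, w, sres, eta, beta, b0, lam, xsq, n,
                                      wsum, screened)
                    if dmax > outer_change:
                        outer_change = dmax
                    if dmax < tol:
                        break
                    active = np.flatnonzero(beta)
                    for _inner in range(max_inner):
                        da, b0 = _sweep(XT, w, sres, eta, beta, b0, lam, xsq, n,
                                        wsum, active)
                        if da > outer_change:
                            outer_change = da
                        if da < tol:
                            break
                if outer_change < tol * 10.0:
                    break
            # KKT check on the features that were screened out
            _gradient(XT, y, eta, g)
            violations = False
            for j in range(p):
                if not ever[j] and abs(g[j]) > lam + tol:
                    in_set[j] = True
                    violations = True
            if not violations:
                break
        lam_prev = lam
        coefs[li] = beta
        intercepts[li] = b0
        # path stopping rules, as in the reference implementation: stop once
        # the training deviance is essentially saturated or the model has
        # grown past dfmax; deeper penalties carry the current solution
        nnz = 0
        for j in range(p):
            if beta[j] != 0.0:
                nnz += 1
        dev = 0.0
        for i in range(n):
            if eta[i] > 30.0:
                dev += eta[i] - y[i] * eta[i]
            else:
                dev += np.log(1.0 + np.exp(eta[i])) - y[i] * eta[i]
        dev = 2.0 * dev / n
        saturated = dev_null > 0.0 and 1.0 - dev / dev_null > 0.99
        if saturated or nnz > dfmax:
            for lj in range(li + 1, nl):
                coefs[lj] = beta
                intercepts[lj] = b0
            break
    return coefs, intercepts


def logistic_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-6,
    max_outer: int = 15,
    max_inner: int = 60,
    dfmax: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and intercepts along a descending penalty grid.

    Returns ``(coefs, intercepts)`` with ``coefs[k]`` the solution at
    ``lambdas[k]``; ``X`` should be standardized and ``y`` in {0, 1} with
    both classes present.  The path stops early once the training deviance
    saturates or the active set exceeds ``dfmax`` (default: no size cap);
    deeper grid points then carry the last computed solution forward.
    """
    XT = np.ascontiguousarray(np.asarray(X, dtype=np.float64).T)
    y = np.asarray(y, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if not np.all(np.diff(lambdas) <= 0):
        raise ValueError("lambda grid must be non-increasing for warm starts")
    if dfmax is None:
        dfmax = XT.shape[0] + 1
    return _logistic_cd_path(XT, y, lambdas, tol, max_outer, max_inner, dfmax)
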