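"""Compiled Newton/IRLS logistic-regression kernels.

The permutation null re-fits every SNP-pair interaction model in every
replicate (order 10^6-10^7 small fits per experiment), so the solver is a
numba-compiled Newton iteration with explicit Cholesky linear algebra rather
than a generic GLM library.  Status codes:

* 0 (OK) — converged, standard errors available;
* 1 (COLLINEAR) — design rank-deficient, statistic undefined;
* 2 (NON_CONVERGED) — separation (a coefficient escaped the dosage-scale
  bound) or no convergence within the iteration cap.

Convergence: max |score| < ``score_tol`` or relative log-likelihood change
< ``ll_tol``; defaults 1e-8 / 1e-10 with a 50-iteration cap and a coefficient
bound of 15.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

OK = 0
COLLINEAR = 1
NON_CONVERGED = 2

MAX_ITER = 50
SCORE_TOL = 1e-8
LL_TOL = 1e-10
BETA_BOUND = 15.0

_GRAM_PIVOT_TOL = 1e-8  # on the column-normalized Gram matrix (unit diagonal)
_HESS_PIVOT_TOL = 1e-12


@njit(cache=True)
def _chol_factor(A, tol):
    """Lower Cholesky of SPD ``A``; flag False when a pivot falls below
    ``tol`` relative to the diagonal (rank deficiency)."""
    n = A.shape[0]
    L = np.zeros_like(A)
    for j in range(n):
        s = A[j, j]
        for k in range(j):
            s -= L[j, k] * L[j, k]
        if A[j, j] <= 0.0 or s <= tol * A[j, j]:
            return L, False
        L[j, j] = math.sqrt(s)
        for i in range(j + 1, n):
            t = A[i, j]
            for k in range(j):
                t -= L[i, k] * L[j, k]
            L[i, j] = t / L[j, j]
    return L, True


@njit(cache=True)
def _chol_solve(L, b):
    """Solve L L^T x = b."""
    n = L.shape[0]
    x = b.copy()
    for i in range(n):
        for k in range(i):
            x[i] -= L[i, k] * x[k]
        x[i] /= L[i, i]
    for i in range(n - 1, -1, -1):
        for k in range(i + 1, n):
            x[i] -= L[k, i] * x[k]
        x[i] /= L[i, i]
    return x


@njit(cache=True)
def _chol_inverse(L):
    n = L.shape[0]
    inv = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        inv[:, j] = _chol_solve(L, e)
    return 0.5 * (inv + inv.T)


@njit(cache=True)
def _log_likelihood(eta, y):
    ll = 0.0
    for i in range(eta.shape[0]):
        e = eta[i]
        # log(1 + exp(e)) computed stably
        if e > 0.0:
            ll += y[i] * e - e - math.log1p(math.exp(-e))
        else:
            ll += y[i] * e - math.log1p(math.exp(e))
    return ll


@njit(cache=True)
def _is_rank_deficient(X):
    """Cholesky pivot test on the column-normalized Gram matrix."""
    n, k = X.shape
    norms = np.empty(k)
    for j in range(k):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        if s <= 0.0:
            return True
        norms[j] = math.sqrt(s)
    G = np.empty((k, k))
    for a in range(k):
        for b in range(a + 1):
            s = 0.0
            for i in range(n):
                s += X[i, a] * X[i, b]
            G[a, b] = s / (norms[a] * norms[b])
            G[b, a] = G[a, b]
    _, ok = _chol_factor(G, _GRAM_PIVOT_TOL)
    return not ok


@njit(cache=True, fastmath=True)
def _score_hessian(X, y, eta, score, H):
    """One fused pass: score and observed information at ``eta``."""
    n, k = X.shape
    for a in range(k):
        score[a] = 0.0
        for b in range(k):
            H[a, b] = 0.0
    for i in range(n):
        e = eta[i]
        if e > 30.0:
            e = 30.0
        elif e < -30.0:
            e = -30.0
        m = 1.0 / (1.0 + math.exp(-e))
        r = y[i] - m
        w = m * (1.0 - m)
        for a in range(k):
            xa = X[i, a]
            score[a] += xa * r
            wa = w * xa
            for b in range(a + 1):
                H[a, b] += wa * X[i, b]
    for a in range(k):
        for b in range(a):
            H[b, a] = H[a, b]


@njit(cache=True, fastmath=True)
def _eta_loglik(X, beta, y, eta):
    """Fill ``eta = X @ beta`` and return the log-likelihood."""
    n, k = X.shape
    ll = 0.0
    for i in range(n):
        s = 0.0
        for a in range(k):
            s += X[i, a] * beta[a]
        eta[i] = s
        if s > 0.0:
            ll += y[i] * s - s - math.log1p(math.exp(-s))
        else:
            ll += y[i] * s - math.log1p(math.exp(s))
    return ll


@njit(cache=True)
def newton_logistic(X, y, max_iter, score_tol, ll_tol, beta_bound, bound_cols=0):
    """Newton-Raphson ML logistic fit with step halving.

    ``bound_cols`` limits the separation bound to the first that many
    columns (0 = all): interaction scans bound only the dosage-model terms,
    whose additive coding fixes their scale, so covariates of arbitrary
    scale cannot spuriously trip it.  Returns (beta, covariance, log_lik,
    n_iterations, status).
    """
    n, k = X.shape
    beta = np.zeros(k)
    cov = np.full((k, k), np.nan)

    if _is_rank_deficient(X):
        return beta, cov, np.nan, 0, COLLINEAR

    # warm start: intercept at the logit of the case fraction (column 0 is
    # assumed to be the intercept; harmless otherwise)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    if 0.0 < ybar < 1.0:
        beta[0] = math.log(ybar / (1.0 - ybar))

    eta = np.empty(n)
    new_eta = np.empty(n)
    score = np.empty(k)
    H = np.empty((k, k))
    ll = _eta_loglik(X, beta, y, eta)
    status = NON_CONVERGED
    niter = 0

    for it in range(1, max_iter + 1):
        niter = it
        _score_hessian(X, y, eta, score, H)
        smax = 0.0
        for j in range(k):
            if abs(score[j]) > smax:
                smax = abs(score[j])
        if smax < score_tol:
            status = OK
            niter = it - 1
            break
        L, ok = _chol_factor(H, _HESS_PIVOT_TOL)
        if not ok:
            status = NON_CONVERGED
            break
        delta = _chol_solve(L, score)
        step = 1.0
        new_beta = beta
        new_ll = ll
        accepted = False
        for _ in range(30):
            new_beta = beta + step * delta
            new_ll = _eta_loglik(X, new_beta, y, new_eta)
            if new_ll >= ll - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            status = NON_CONVERGED
            break
        ll_prev = ll
        beta = new_beta
        eta, new_eta = new_eta, eta
        ll = new_ll
        kb = k if bound_cols <= 0 else min(bound_cols, k)
        bmax = 0.0
        for j in range(kb):
            if abs(beta[j]) > bmax:
                bmax = abs(beta[j])
        if bmax > beta_bound:
            status = NON_CONVERGED
            break
        if abs(ll - ll_prev) < ll_tol * (abs(ll) + 1e-30):
            status = OK
            break

    if status == OK:
        _score_hessian(X, y, eta, score, H)
        L, ok = _chol_factor(H, _HESS_PIVOT_TOL)
        if not ok:
            status = NON_CONVERGED
        else:
            cov = _chol_inverse(L)
    return beta, cov, ll, niter, status


@njit(cache=True)
def wald_p(z):
    """Two-sided p-value of a standard-normal deviate."""
    return math.erfc(abs(z) / math.sqrt(2.0))


@njit(cache=True)
def scan_pairs(DA, DB, C, y, max_iter, score_tol, ll_tol, beta_bound):
    """All index x partner interaction fits on complete data.

    Design per pair: [1, d_A, d_B, d_A*d_B, covariates].  Returns
    (beta3, se3, p, status) arrays of shape (n_index, n_partner).
    """
    n = DA.shape[0]
    na = DA.shape[1]
    nb = DB.shape[1]
    c = C.shape[1]
    k = 4 + c
    X = np.empty((n, k))
    for i in range(n):
        X[i, 0] = 1.0
        for j in range(c):
            X[i, 4 + j] = C[i, j]
    beta3 = np.full((na, nb), np.nan)
    se3 = np.full((na, nb), np.nan)
    pvals = np.full((na, nb), np.nan)
    status = np.zeros((na, nb), dtype=np.int8)
    for a in range(na):
        for i in range(n):
            X[i, 1] = DA[i, a]
        for b in range(nb):
            for i in range(n):
                X[i, 2] = DB[i, b]
                X[i, 3] = DA[i, a] * DB[i, b]
            beta, cov, _ll, _it, st = newton_logistic(
                X, y, max_iter, score_tol, ll_tol, beta_bound, 4
            )
            status[a, b] = st
            if st == OK:
                v = cov[3, 3]
                if v > 0.0:
                    beta3[a, b] = beta[3]
                    se3[a, b] = math.sqrt(v)
                    pvals[a, b] = wald_p(beta[3] / se3[a, b])
                else:
                    status[a, b] = NON_CONVERGED
    return beta3, se3, pvals, status


@njit(cache=True)
def newton_logistic_grouped(Xc, cnt, cases, max_iter, score_tol, ll_tol, beta_bound):
    """Newton ML logistic fit on grouped (binomial) data.

    ``Xc`` holds one design row per distinct covariate pattern, ``cnt`` the
    pattern multiplicities and ``cases`` the case counts per pattern.  The
    log-likelihood is the ungrouped Bernoulli one (no binomial constant), so
    estimates, standard errors and convergence behaviour match
    :func:`newton_logistic` on the expanded data.
    """
    m, k = Xc.shape
    beta = np.zeros(k)
    cov = np.full((k, k), np.nan)

    # rank check on the count-weighted Gram (equals the ungrouped Gram)
    norms = np.empty(k)
    G = np.empty((k, k))
    for a in range(k):
        s = 0.0
        for i in range(m):
            s += cnt[i] * Xc[i, a] * Xc[i, a]
        if s <= 0.0:
            return beta, cov, np.nan, 0, COLLINEAR
        norms[a] = math.sqrt(s)
    for a in range(k):
        for b in range(a + 1):
            s = 0.0
            for i in range(m):
                s += cnt[i] * Xc[i, a] * Xc[i, b]
            G[a, b] = s / (norms[a] * norms[b])
            G[b, a] = G[a, b]
    _, ok = _chol_factor(G, _GRAM_PIVOT_TOL)
    if not ok:
        return beta, cov, np.nan, 0, COLLINEAR

    ncase = 0.0
    ntot = 0.0
    for i in range(m):
        ncase += cases[i]
        ntot += cnt[i]
    ybar = ncase / ntot
    if 0.0 < ybar < 1.0:
        beta[0] = math.log(ybar / (1.0 - ybar))

    eta = np.empty(m)
    new_eta = np.empty(m)
    score = np.empty(k)
    H = np.empty((k, k))

    ll = 0.0
    for i in range(m):
        s = 0.0
        for a in range(k):
            s += Xc[i, a] * beta[a]
        eta[i] = s
        if s > 0.0:
            ll += cases[i] * s - cnt[i] * (s + math.log1p(math.exp(-s)))
        else:
            ll += cases[i] * s - cnt[i] * math.log1p(math.exp(s))

    status = NON_CONVERGED
    niter = 0
    for it in range(1, max_iter + 1):
        niter = it
        for a in range(k):
            score[a] = 0.0
            for b in range(k):
                H[a, b] = 0.0
        for i in range(m):
            e = eta[i]
            if e > 30.0:
                e = 30.0
            elif e < -30.0:
                e = -30.0
            mu = 1.0 / (1.0 + math.exp(-e))
            r = cases[i] - cnt[i] * mu
            w = cnt[i] * mu * (1.0 - mu)
            for a in range(k):
                xa = Xc[i, a]
                score[a] += xa * r
                wa = w * xa
                for b in range(a + 1):
                    H[a, b] += wa * Xc[i, b]
        for a in range(k):
            for b in range(a):
                H[b, a] = H[a, b]
        smax = 0.0
        for j in range(k):
            if abs(score[j]) > smax:
                smax = abs(score[j])
        if smax < score_tol:
            status = OK
            niter = it - 1
            break
        L, ok2 = _chol_factor(H, _HESS_PIVOT_TOL)
        if not ok2:
            status = NON_CONVERGED
            break
        delta = _chol_solve(L, score)
        step = 1.0
        new_beta = beta
        new_ll = ll
        accepted = False
        for _ in range(30):
            new_beta = beta + step * delta
            new_ll = 0.0
            for i in range(m):
                s = 0.0
                for a in range(k):
                    s += Xc[i, a] * new_beta[a]
                new_eta[i] = s
                if s > 0.0:
                    new_ll += cases[i] * s - cnt[i] * (s + math.log1p(math.exp(-s)))
                else:
                    new_ll += cases[i] * s - cnt[i] * math.log1p(math.exp(s))
            if new_ll >= ll - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            status = NON_CONVERGED
            break
        ll_prev = ll
        beta = new_beta
        eta, new_eta = new_eta, eta
        ll = new_ll
        bmax = 0.0
        for j in range(k):
            if abs(beta[j]) > bmax:
                bmax = abs(beta[j])
        if bmax > beta_bound:
            status = NON_CONVERGED
            break
        if abs(ll - ll_prev) < ll_tol * (abs(ll) + 1e-30):
            status = OK
            break

    if status == OK:
        for a in range(k):
            for b in range(k):
                H[a, b] = 0.0
        for i in range(m):
            e = eta[i]
            if e > 30.0:
                e = 30.0
            elif e < -30.0:
                e = -30.0
            mu = 1.0 / (1.0 + math.exp(-e))
            w = cnt[i] * mu * (1.0 - mu)
            for a in range(k):
                wa = w * Xc[i, a]
                for b in range(a + 1):
                    H[a, b] += wa * Xc[i, b]
        for a in range(k):
            for b in range(a):
                H[b, a] = H[a, b]
        L, ok3 = _chol_factor(H, _HESS_PIVOT_TOL)
        if not ok3:
            status = NON_CONVERGED
        else:
            cov = _chol_inverse(L)
    return beta, cov, ll, niter, status


@njit(cache=True)
def scan_pairs_hard(GA, GB, y, max_iter, score_tol, ll_tol, beta_bound):
    """Interaction scan on hard (integer {0,1,2}) dosages, no covariates.

    Mathematically identical to :func:`scan_pairs` with empty covariates:
    each pair's likelihood is collapsed onto the 3x3 genotype table, making
    the per-fit cost independent of sample size.
    """
    n = GA.shape[0]
    na = GA.shape[1]
    nb = GB.shape[1]
    beta3 = np.full((na, nb), np.nan)
    se3 = np.full((na, nb), np.nan)
    pvals = np.full((na, nb), np.nan)
    status = np.zeros((na, nb), dtype=np.int8)
    cnt = np.empty(9)
    cases = np.empty(9)
    Xc = np.empty((9, 4))
    for a in range(na):
        for b in range(nb):
            for c in range(9):
                cnt[c] = 0.0
                cases[c] = 0.0
            for i in range(n):
                c = int(GA[i, a]) * 3 + int(GB[i, b])
                cnt[c] += 1.0
                cases[c] += y[i]
            m = 0
            for c in range(9):
                if cnt[c] > 0.0:
                    ga = c // 3
                    gb = c % 3
                    Xc[m, 0] = 1.0
                    Xc[m, 1] = ga
                    Xc[m, 2] = gb
                    Xc[m, 3] = ga * gb
                    cnt[m] = cnt[c]
                    cases[m] = cases[c]
                    m += 1
            beta, cov, _ll, _it, st = newton_logistic_grouped(
                Xc[:m], cnt[:m], cases[:m], max_iter, score_tol, ll_tol, beta_bound
            )
            status[a, b] = st
            if st == OK:
                v = cov[3, 3]
                if v > 0.0:
                    beta3[a, b] = beta[3]
                    se3[a, b] = math.sqrt(v)
                    pvals[a, b] = wald_p(beta[3] / se3[a, b])
                else:
                    status[a, b] = NON_CONVERGED
    return beta3, se3, pvals, status


@njit(cache=True)
def scan_min_p_hard(GA, GB, y, max_iter, score_tol, ll_tol, beta_bound):
    """Minimum OK p over a hard-dosage gene-pair scan; NaN when none OK."""
    _b3, _se, pvals, status = scan_pairs_hard(
        GA, GB, y, max_iter, score_tol, ll_tol, beta_bound
    )
    best = np.inf
    found = False
    for a in range(pvals.shape[0]):
        for b in range(pvals.shape[1]):
            if status[a, b] == OK and pvals[a, b] < best:
                best = pvals[a, b]
                found = True
    if not found:
        return np.nan
    return best


@njit(cache=True)
def scan_min_p(DA, DB, C, y, max_iter, score_tol, ll_tol, beta_bound):
    """Minimum OK p over one gene pair scan; NaN when no OK test."""
    _b3, _se, pvals, status = scan_pairs(
        DA, DB, C, y, max_iter, score_tol, ll_tol, beta_bound
    )
    best = np.inf
    found = False
    for a in range(pvals.shape[0]):
        for b in range(pvals.shape[1]):
            if status[a, b] == OK and pvals[a, b] < best:
                best = pvals[a, b]
                found = True
    if not found:
        return np.nan
    return best
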