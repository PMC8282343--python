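"""Elastic-net solver used by the transcriptional-signature models.

Gaussian elastic net in the glmnet parameterisation,

    (1/2n) * ||y - X b||^2  +  lambda * ( alpha*||b||_1 + (1-alpha)/2*||b||^2 ),

solved by cyclic coordinate descent on the Gram matrix ``G = X'X`` with
sequential strong-rule screening, covariance updates over the screened set,
and warm starts along a descending lambda path.  Screening is safe: after
convergence on the screened set a full KKT pass admits any violator and
iterates, so solutions are exact to the stated tolerance.  Working on the
Gram makes a fold's problem a cheap rank-k update of the full-data problem,
which keeps true leave-one-out cross-validation affordable at n ~ 250,
p ~ 2000.

Inputs are assumed column-standardized (the caller handles scaling and the
intercept); ``y`` is centered.  Convergence follows the glmnet criterion:
stop when the largest single-coordinate objective change in a sweep falls
below ``tol * y'y``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _path_cd(G, Xy, n, lambdas, alpha, thr, max_iter,
             betas_out, store_betas,
             Xo, yo, pred_out, mse_out, do_pred, patience):
    """Warm-started path solve; optionally score held-out samples.

    G, Xy        : Gram and X'y of the *training* data (n samples).
    betas_out    : (p, L) filled when store_betas is True.
    Xo, yo       : held-out block scored per lambda when do_pred is True.
    patience     : with do_pred, stop the path after this many consecutive
                   lambdas whose held-out MSE exceeds the running minimum
                   (remaining mse_out entries are set to +inf).  patience<=0
                   disables early stopping.
    Returns the index of the last lambda solved.
    """
    p = G.shape[0]
    L = lambdas.shape[0]
    m = Xo.shape[0]
    beta = np.zeros(p)
    qa = np.zeros(p)          # qa[j] = sum_{k in act} G[j,k] beta[k], j in S
    rho_all = Xy.copy()       # KKT residuals at current beta, all j
    inS = np.zeros(p, np.uint8)
    S = np.empty(p, np.int64)
    act_mask = np.zeros(p, np.uint8)
    act = np.empty(p, np.int64)
    n_act = 0
    best_mse = np.inf
    n_worse = 0
    last_l = L - 1
    for l in range(L):
        lam = lambdas[l]
        nl1 = n * lam * alpha
        nl2 = n * lam * (1.0 - alpha)
        lam_prev = lambdas[l - 1] if l > 0 else lambdas[0]
        # sequential strong rule: |rho_j(prev)| >= n*alpha*(2*lam - lam_prev)
        cut = n * alpha * (2.0 * lam - lam_prev)
        nS = 0
        for j in range(p):
            if act_mask[j] or abs(rho_all[j]) >= cut:
                inS[j] = 1
                S[nS] = j
                nS += 1
        for _round in range(max_iter):
            # qa over S given current active set
            for jj in range(nS):
                j = S[jj]
                s = 0.0
                for kk in range(n_act):
                    k = act[kk]
                    bk = beta[k]
                    if bk != 0.0:
                        s += G[j, k] * bk
                qa[j] = s
            # converge on S; coordinates entering join act
            for _it in range(max_iter):
                maxd = 0.0
                for jj in range(nS):
                    j = S[jj]
                    gjj = G[j, j]
                    if gjj <= 0.0:
                        continue
                    rho = Xy[j] - qa[j] + gjj * beta[j]
                    if rho > nl1:
                        bnew = (rho - nl1) / (gjj + nl2)
                    elif rho < -nl1:
                        bnew = (rho + nl1) / (gjj + nl2)
                    else:
                        bnew = 0.0
                    d = bnew - beta[j]
                    if d != 0.0:
                        beta[j] = bnew
                        if not act_mask[j]:
                            act_mask[j] = 1
                            act[n_act] = j
                            n_act += 1
                        for kk in range(nS):
                            k = S[kk]
                            qa[k] += d * G[k, j]
                        dd = gjj * d * d
                        if dd > maxd:
                            maxd = dd
                if maxd < thr:
                    break
            # full KKT pass (exactness guard for the strong rule)
            viol = False
            for j in range(p):
                s = 0.0
                for kk in range(n_act):
                    k = act[kk]
                    bk = beta[k]
                    if bk != 0.0:
                        s += G[j, k] * bk
                rho_all[j] = Xy[j] - s
                if inS[j]:
                    continue
                gjj = G[j, j]
                if gjj <= 0.0:
                    continue
                av = abs(rho_all[j])
                if av > nl1:
                    d = (av - nl1) / (gjj + nl2)
                    if gjj * d * d > thr:
                        inS[j] = 1
                        S[nS] = j
                        nS += 1
                        viol = True
            if not viol:
                break
        # clear S membership for next lambda (act_mask persists)
        for jj in range(nS):
            inS[S[jj]] = 0
        if store_betas:
            for j in range(p):
                betas_out[j, l] = beta[j]
        if do_pred:
            err = 0.0
            for i in range(m):
                s = 0.0
                for kk in range(n_act):
                    k = act[kk]
                    bk = beta[k]
                    if bk != 0.0:
                        s += Xo[i, k] * bk
                pred_out[i, l] = s
                err += (yo[i] - s) ** 2
            mse = err / m
            mse_out[l] = mse
            if mse < best_mse:
                best_mse = mse
                n_worse = 0
            else:
                n_worse += 1
                if patience > 0 and n_worse >= patience:
                    for l2 in range(l + 1, L):
                        mse_out[l2] = np.inf
                    last_l = l
                    break
    return last_l


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
) -> np.ndarray:
    """Descending log-spaced grid from the data-derived lambda_max.

    lambda_max is the smallest penalty at which all coefficients are zero:
    max_j |x_j . y| / (n * alpha).  The default lambda_min_ratio follows the
    glmnet convention: 1e-2 when n < p, else 1e-4.
    """
    n, p = X.shape
    if lambda_min_ratio is None:
        lambda_min_ratio = 1e-2 if n < p else 1e-4
    a = max(alpha, 1e-3)  # guard for near-ridge mixing
    lmax = np.max(np.abs(X.T @ y)) / (n * a)
    if lmax <= 0:
        lmax = 1.0
    return lmax * np.logspace(0, np.log10(lambda_min_ratio), n_lambda)


# placeholder held-out arrays for pure path solves (do_pred=False)
_EMPTY_ROWS = np.empty((0, 1))
_EMPTY_VEC = np.empty(0)
_EMPTY_MSE = np.empty(0)


def enet_path_gram(
    G: np.ndarray,
    Xy: np.ndarray,
    n: int,
    lambdas: np.ndarray,
    alpha: float,
    yty: float,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> np.ndarray:
    """Solve the path (descending lambdas, warm starts). Returns p x L betas."""
    p = G.shape[0]
    L = len(lambdas)
    betas = np.zeros((p, L))
    thr = tol * max(yty, 1e-12)
    _path_cd(np.ascontiguousarray(G), np.ascontiguousarray(Xy, dtype=np.float64),
             n, np.ascontiguousarray(lambdas, dtype=np.float64), alpha, thr,
             max_iter, betas, True,
             _EMPTY_ROWS, _EMPTY_VEC, _EMPTY_ROWS, _EMPTY_MSE,
             False, 0)
    return betas


def make_folds(n: int, n_folds: int) -> list[np.ndarray]:
    """Deterministic contiguous fold index sets (n_folds == n gives LOO)."""
    return [idx for idx in np.array_split(np.arange(n), n_folds) if len(idx)]


def cv_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    folds: list[np.ndarray],
    tol: float = 1e-7,
    max_iter: int = 1000,
    G: np.ndarray | None = None,
    fold_grams: list[np.ndarray] | None = None,
    patience: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-validated MSE along the path (true per-fold path solves).

    Returns (cv_mse[L], cv_mse_sd[L], pred[n, L]); pred holds the held-out
    predictions (centered-y scale).  With ``patience > 0`` a fold's path
    stops after that many consecutive lambdas past its held-out-MSE minimum
    (unvisited entries count as +inf and never win model selection).
    ``fold_grams`` may carry precomputed ``G - X_out' X_out`` per fold for
    reuse across repeated calls with the same X and folds.
    """
    n, p = X.shape
    L = len(lambdas)
    if G is None:
        G = X.T @ X
    Xy = X.T @ y
    yty = float(y @ y)
    thr = tol * max(yty, 1e-12)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)

    pred = np.full((n, L), np.nan)
    fold_mse = np.empty((len(folds), L))
    dummy_b = np.zeros((1, 1))
    gbuf = np.empty_like(G)
    col_sums = X.sum(axis=0)
    y_sum = float(y.sum())
    for f, out in enumerate(folds):
        Xo = np.ascontiguousarray(X[out])
        yo = np.ascontiguousarray(y[out], dtype=np.float64)
        nf = n - len(out)
        # re-center the training fold (removes the held-out samples'
        # contribution to the column means -- avoids optimistic CV)
        mu_f = (col_sums - Xo.sum(axis=0)) / nf
        ybar_f = (y_sum - yo.sum()) / nf
        if fold_grams is not None:
            Gf = fold_grams[f]
        else:
            np.subtract(G, Xo.T @ Xo, out=gbuf)
            gbuf -= nf * np.outer(mu_f, mu_f)
            Gf = gbuf
        sf = nf * mu_f
        Xyf = Xy - Xo.T @ yo - sf * ybar_f
        Xoc = np.ascontiguousarray(Xo - mu_f)
        yoc = yo - ybar_f
        po = np.full((len(out), L), np.nan)
        mo = np.empty(L)
        _path_cd(Gf, Xyf, nf, lambdas, alpha, thr, max_iter,
                 dummy_b, False, Xoc, yoc, po, mo, True, patience)
        pred[out, :] = po + ybar_f
        fold_mse[f, :] = mo
    # lambdas every fold visited get the pooled MSE; others are +inf
    visited = np.isfinite(fold_mse).all(axis=0)
    cv_mse = np.full(L, np.inf)
    with np.errstate(invalid="ignore"):
        sq = (y[:, None] - pred) ** 2
    cv_mse[visited] = np.nanmean(sq[:, visited], axis=0)
    cv_sd = np.full(L, np.nan)
    if len(folds) > 1:
        cv_sd[visited] = fold_mse[:, visited].std(axis=0, ddof=1) / np.sqrt(
            len(folds)
        )
    return cv_mse, cv_sd, pred


def precompute_fold_grams(X: np.ndarray, folds: list[np.ndarray],
                          G: np.ndarray | None = None) -> list[np.ndarray]:
    """Per-fold training Grams with the fold re-centering applied."""
    if G is None:
        G = X.T @ X
    n = X.shape[0]
    col_sums = X.sum(axis=0)
    out_list = []
    for out in folds:
        Xo = X[out]
        nf = n - len(out)
        mu_f = (col_sums - Xo.sum(axis=0)) / nf
        out_list.append(np.ascontiguousarray(
            G - Xo.T @ Xo - nf * np.outer(mu_f, mu_f)
        ))
    return out_list
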