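"""Penalized outcome models for high-dimensional mediator selection.

Two fits of the outcome on all screened probes jointly (with exposure and
covariates unpenalized):

* de-sparsified / de-biased LASSO — LASSO point estimate corrected via
  nodewise regression so that every probe gets an asymptotically normal
  estimate, standard error and Wald p-value even when p > n;
* minimax concave penalty (MCP) — nonconvex selection with reduced
  shrinkage bias; survivors are refit by OLS for inference.

Unpenalized columns are handled by Frisch-Waugh partialling: the outcome
and every probe are residualized on [intercept, exposure, covariates]
before the penalized fit, and probe columns are standardized internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

__all__ = [
    "DebiasedLassoResult",
    "McpResult",
    "fit_debiased_lasso",
    "fit_mcp",
    "mcp_threshold",
]


# --------------------------------------------------------------------------
# shared helpers
# --------------------------------------------------------------------------

def _as_matrix(M):
    if hasattr(M, "beta"):
        M = M.beta
    if hasattr(M, "columns"):
        return np.asarray(M, dtype=float), list(M.columns)
    X = np.asarray(M, dtype=float)
    return X, [f"p{i}" for i in range(X.shape[1])]


def _unpenalized_design(n: int, exposure, covariates) -> np.ndarray:
    cols = [np.ones(n)]
    if exposure is not None:
        cols.append(np.asarray(exposure, dtype=float))
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    return np.column_stack(cols)


def _partial_out(y, X, U):
    # SVD-based projection is safe when U is rank-deficient
    coef_y, *_ = np.linalg.lstsq(U, y, rcond=None)
    coef_X, *_ = np.linalg.lstsq(U, X, rcond=None)
    return y - U @ coef_y, X - U @ coef_X


def _standardize(X):
    scale = X.std(axis=0)
    scale_safe = np.where(scale > 0, scale, 1.0)
    return X / scale_safe, scale_safe, scale == 0


# --------------------------------------------------------------------------
# de-biased LASSO
# --------------------------------------------------------------------------

@dataclass
class DebiasedLassoResult:
    probe_ids: list[str]
    beta: np.ndarray          # de-biased estimates, original probe scale
    se: np.ndarray
    p: np.ndarray             # two-sided Wald p-values
    lasso_coef: np.ndarray    # raw LASSO estimates, original probe scale
    selected: np.ndarray      # probes with nonzero LASSO coefficient
    alpha: float
    sigma: float


def fit_debiased_lasso(
    Y,
    M,
    exposure=None,
    covariates=None,
    alpha: float | None = None,
    nodewise_alpha: float | str | None = None,
    cv: int = 10,
    seed: int = 0,
) -> DebiasedLassoResult:
    """De-biased LASSO of the outcome on screened probes.

    The LASSO penalty is chosen by ``cv``-fold cross-validation
    (minimum-CV rule) unless ``alpha`` is given; ``alpha=0`` reduces to
    OLS.  De-biasing uses nodewise LASSO rows with a fixed universal
    penalty ``0.5 * sqrt(log p / n)`` on standardized columns
    (``nodewise_alpha='cv'`` switches to per-column cross-validation).
    """
    X, probe_ids = _as_matrix(M)
    y = np.asarray(Y, dtype=float).ravel()
    n, p = X.shape
    if y.std() == 0:
        raise ValueError("outcome has zero variance")
    if n < 10:
        raise ValueError("need at least 10 samples")

    U = _unpenalized_design(n, exposure, covariates)
    k_unpen = U.shape[1]
    y_t, X_t = _partial_out(y, X, U)
    Xs, scale, is_const = _standardize(X_t)

    if alpha == 0.0:
        coef, *_ = np.linalg.lstsq(Xs, y_t, rcond=None)
        resid = y_t - Xs @ coef
        dof = max(n - k_unpen - p, 1)
        sigma = float(np.sqrt(resid @ resid / dof))
        xtx_inv = np.linalg.pinv(Xs.T @ Xs)
        se_std = sigma * np.sqrt(np.diag(xtx_inv))
        beta = coef / scale
        se = se_std / scale
        z = np.where(se > 0, beta / se, 0.0)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        return DebiasedLassoResult(
            probe_ids, beta, se, pvals, beta.copy(),
            np.ones(p, dtype=bool), 0.0, sigma,
        )

    if alpha is None:
        folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
        las = LassoCV(cv=folds, alphas=60, max_iter=5000).fit(Xs, y_t)
        alpha_used = float(las.alpha_)
        coef = las.coef_.copy()
    else:
        alpha_used = float(alpha)
        las = Lasso(alpha=alpha_used, max_iter=5000).fit(Xs, y_t)
        coef = las.coef_.copy()

    resid = y_t - Xs @ coef
    s_hat = int(np.count_nonzero(coef))
    dof = max(n - k_unpen - s_hat, 1)
    sigma = float(np.sqrt(resid @ resid / dof))

    # nodewise regression rows of the approximate precision matrix
    Sigma_hat = Xs.T @ Xs / n
    Theta = np.zeros((p, p))
    if p == 1:
        tau2 = max(float(Sigma_hat[0, 0]), 1e-12)
        Theta[0, 0] = 1.0 / tau2
    else:
        if nodewise_alpha is None:
            a_nw = 0.5 * np.sqrt(np.log(p) / n)
        elif nodewise_alpha == "cv":
            a_nw = None
        else:
            a_nw = float(nodewise_alpha)
        idx_all = np.arange(p)
        for j in range(p):
            others = idx_all != j
            Xj = Xs[:, j]
            Xo = Xs[:, others]
            if a_nw is None:
                folds = KFold(n_splits=min(cv, 5), shuffle=True, random_state=seed + j)
                nw = LassoCV(cv=folds, alphas=30, max_iter=3000).fit(Xo, Xj)
                gamma = nw.coef_
                a_j = float(nw.alpha_)
            else:
                nw = Lasso(alpha=a_nw, max_iter=3000).fit(Xo, Xj)
                gamma = nw.coef_
                a_j = a_nw
            r_j = Xj - Xo @ gamma
            tau2 = float(r_j @ r_j) / n + a_j * float(np.abs(gamma).sum())
            tau2 = max(tau2, 1e-12)
            row = np.zeros(p)
            row[j] = 1.0
            row[others] = -gamma
            Theta[j] = row / tau2

    b_deb_std = coef + Theta @ (Xs.T @ resid) / n
    var_std = np.einsum("ij,jk,ik->i", Theta, Sigma_hat, Theta) / n
    se_std = sigma * np.sqrt(np.maximum(var_std, 0.0))

    beta = np.where(is_const, 0.0, b_deb_std / scale)
    se = np.where(is_const, np.inf, se_std / scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.where(is_const, 1.0, pvals)

    return DebiasedLassoResult(
        probe_ids,
        beta,
        se,
        pvals,
        np.where(is_const, 0.0, coef / scale),
        coef != 0,
        alpha_used,
        sigma,
    )


# --------------------------------------------------------------------------
# MCP coordinate descent
# --------------------------------------------------------------------------

def mcp_threshold(z: np.ndarray, lam: float, gamma: float) -> np.ndarray:
    """Closed-form MCP solution for a unit-variance orthonormal design."""
    z = np.asarray(z, dtype=float)
    soft = np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)
    firm = soft / (1.0 - 1.0 / gamma)
    return np.where(np.abs(z) <= gamma * lam, firm, z)


@njit(cache=False)
def _mcp_sweep(G, xty, lam, gamma, beta, grad, active_only):  # pragma: no cover
    # one coordinate-descent sweep on the Gram system; grad = xty - G @ beta
    p = beta.size
    max_delta = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        z = bj + grad[j]
        az = abs(z)
        if az <= gamma * lam:
            s = az - lam
            if s < 0.0:
                s = 0.0
            new = (s / (1.0 - 1.0 / gamma)) * (1.0 if z >= 0 else -1.0)
        else:
            new = z
        d = new - bj
        if d != 0.0:
            beta[j] = new
            for k in range(p):
                grad[k] -= G[k, j] * d
            ad = abs(d)
            if ad > max_delta:
                max_delta = ad
    return max_delta


@njit(cache=False)
def _mcp_cd_gram(G, xty, lam, gamma, beta, max_iter, tol):  # pragma: no cover
    grad = xty - G @ beta
    for _ in range(max_iter):
        # iterate on the active set until stable, then one full sweep
        for _ in range(max_iter):
            delta = _mcp_sweep(G, xty, lam, gamma, beta, grad, True)
            if delta < tol:
                break
        delta = _mcp_sweep(G, xty, lam, gamma, beta, grad, False)
        if delta < tol:
            break
    return beta


def _mcp_cd(X, y, lam, gamma, beta, max_iter, tol):
    n = X.shape[0]
    G = X.T @ X / n
    xty = X.T @ y / n
    return _mcp_cd_gram(G, xty, float(lam), float(gamma), beta, max_iter, tol)


def _mcp_path_gram(G, xty, lambdas, gamma, max_iter=200, tol=1e-6):
    p = xty.size
    beta = np.zeros(p)
    out = np.zeros((len(lambdas), p))
    for i, lam in enumerate(lambdas):
        beta = _mcp_cd_gram(G, xty, float(lam), float(gamma), beta.copy(), max_iter, tol)
        out[i] = beta
    return out


@dataclass
class McpResult:
    probe_ids: list[str]
    mcp_coef: np.ndarray      # penalized estimates, original probe scale
    selected: np.ndarray      # nonzero MCP coefficients
    beta: np.ndarray          # OLS refit estimates (NaN for non-survivors)
    p: np.ndarray             # refit t-test p-values (NaN for non-survivors)
    alpha: float
    gamma: float
    dropped_covariates: list[int] = field(default_factory=list)


def fit_mcp(
    Y,
    M,
    exposure=None,
    covariates=None,
    gamma: float = 3.0,
    alpha: float | None = None,
    cv: int = 10,
    n_lambdas: int = 25,
    lambda_min_ratio: float = 0.05,
    seed: int = 0,
) -> McpResult:
    """MCP-penalized outcome model with OLS refit of the survivors.

    The penalty level is chosen by ``cv``-fold cross-validation over a
    geometric path (minimum-CV rule) unless ``alpha`` is given;
    ``alpha=0`` reduces to OLS.  Survivors (nonzero MCP coefficients) are
    refit jointly by OLS together with the unpenalized exposure and
    covariates to obtain t-test p-values.
    """
    if gamma <= 1.0:
        raise ValueError("MCP gamma must exceed 1")
    X, probe_ids = _as_matrix(M)
    y = np.asarray(Y, dtype=float).ravel()
    n, p = X.shape
    if y.std() == 0:
        raise ValueError("outcome has zero variance")

    U = _unpenalized_design(n, exposure, covariates)
    y_t, X_t = _partial_out(y, X, U)
    Xs, scale, is_const = _standardize(X_t)

    if alpha == 0.0:
        coef, *_ = np.linalg.lstsq(Xs, y_t, rcond=None)
        mcp_coef = coef / scale
        alpha_used = 0.0
    else:
        if alpha is None:
            lam_max = float(np.abs(Xs.T @ y_t).max() / n)
            lam_max = max(lam_max, 1e-12)
            lambdas = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambdas)
            folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
            cv_err = np.zeros(len(lambdas))
            for tr, te in folds.split(Xs):
                Xtr = Xs[tr]
                fold_scale = Xtr.std(axis=0)
                fold_scale = np.where(fold_scale > 0, fold_scale, 1.0)
                Xtr = Xtr / fold_scale
                ntr = Xtr.shape[0]
                G = Xtr.T @ Xtr / ntr
                xty = Xtr.T @ y_t[tr] / ntr
                path = _mcp_path_gram(G, xty, lambdas, gamma)
                Xte = Xs[te] / fold_scale
                pred_err = ((y_t[te][None, :] - path @ Xte.T) ** 2).mean(axis=1)
                cv_err += pred_err
            alpha_used = float(lambdas[int(np.argmin(cv_err))])
        else:
            alpha_used = float(alpha)
        G_full = Xs.T @ Xs / n
        xty_full = Xs.T @ y_t / n
        coef = _mcp_cd_gram(
            G_full, xty_full, alpha_used, float(gamma), np.zeros(p), 2000, 1e-8
        )
        mcp_coef = np.where(is_const, 0.0, coef / scale)

    selected = (mcp_coef != 0) & ~is_const

    beta = np.full(p, np.nan)
    pvals = np.full(p, np.nan)
    if selected.any():
        surv = np.flatnonzero(selected)
        design = np.column_stack([U, X[:, surv]])
        q = design.shape[1]
        coef_r, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef_r
        dof = max(n - q, 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.pinv(design.T @ design)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        for pos, j in enumerate(surv):
            idx = U.shape[1] + pos
            beta[j] = coef_r[idx]
            if se[idx] > 0:
                t = coef_r[idx] / se[idx]
                pvals[j] = 2.0 * stats.t.sf(abs(t), dof)
            else:
                pvals[j] = 0.0

    return McpResult(
        probe_ids, mcp_coef, selected, beta, pvals, alpha_used, float(gamma)
    )
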