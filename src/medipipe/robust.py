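"""MM-regression: high-breakdown robust linear regression.

An S-estimator with Tukey bisquare rho (50% breakdown) provides the
initial coefficients and the robust residual scale; an iterated M-step
with a bisquare psi tuned to the requested normal efficiency (default
95%) then refines the coefficients at fixed scale.  This is the
estimator used in place of OLS when mediation regressions must resist
outliers and skewed residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, stats

__all__ = ["MMRegressionResult", "fit_mm_regression", "bisquare_tuning_constant"]

# bisquare constant for 50% breakdown: E_Phi[rho_c(Z)] = 0.5 * rho_c(c)
BISQUARE_C_50_BREAKDOWN = 1.547645


class ConvergenceError(RuntimeError):
    """IRWLS failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_coefficients=None):
        super().__init__(message)
        self.last_coefficients = last_coefficients


def _rho_bisquare(u, c):
    v = np.clip(u / c, -1.0, 1.0)
    return (c**2 / 6.0) * (1.0 - (1.0 - v**2) ** 3)


def _psi_bisquare(u, c):
    out = np.zeros_like(u, dtype=float)
    inside = np.abs(u) <= c
    ui = u[inside]
    out[inside] = ui * (1.0 - (ui / c) ** 2) ** 2
    return out


def _weight_bisquare(u, c):
    w = np.zeros_like(u, dtype=float)
    inside = np.abs(u) <= c
    w[inside] = (1.0 - (u[inside] / c) ** 2) ** 2
    return w


@lru_cache(maxsize=32)
def bisquare_tuning_constant(efficiency: float) -> float:
    """Bisquare psi constant achieving the given normal efficiency."""
    if not 0.5 < efficiency < 1.0:
        raise ValueError("efficiency must be in (0.5, 1)")

    def eff(c):
        epsi2 = integrate.quad(
            lambda z: _psi_bisquare(np.array([z]), c)[0] ** 2 * stats.norm.pdf(z),
            -c, c,
        )[0]
        epsip = integrate.quad(
            lambda z: (1 - (z / c) ** 2) * (1 - 5 * (z / c) ** 2) * stats.norm.pdf(z),
            -c, c,
        )[0]
        return epsip**2 / epsi2

    return float(optimize.brentq(lambda c: eff(c) - efficiency, 1.6, 12.0))


def _m_scale(residuals, c, b, s0=None, tol=1e-10, max_iter=200):
    """Solve (1/n) sum rho(r/s) = b for s (bisquare M-scale)."""
    r = np.asarray(residuals, dtype=float)
    nz = np.abs(r) > 0
    if not nz.any():
        return 0.0
    s = float(np.median(np.abs(r[nz])) / 0.6745) if s0 is None else float(s0)
    if s <= 0:
        s = float(np.abs(r[nz]).mean())
    for _ in range(max_iter):
        mean_rho = _rho_bisquare(r / s, c).mean()
        s_new = s * np.sqrt(mean_rho / b)
        if abs(s_new - s) <= tol * s:
            return float(s_new)
        s = float(s_new)
    return float(s)


def _irwls(X, y, beta0, scale, c, tol, max_iter):
    beta = beta0.copy()
    for it in range(max_iter):
        r = y - X @ beta
        u = r / scale
        w = _weight_bisquare(u, c)
        w = np.maximum(w, 0.0)
        if w.sum() <= X.shape[1]:
            # nearly all observations down-weighted to zero: fall back
            w = w + 1e-6
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(Xw.T @ X + 1e-12 * np.eye(X.shape[1]), Xw.T @ y)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        denom = max(np.max(np.abs(beta)), 1.0)
        if delta < tol * denom:
            return beta, it + 1, True
    return beta, max_iter, False


@dataclass
class MMRegressionResult:
    coefficients: np.ndarray
    scale: float
    weights: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    efficiency: float
    n_iter: int
    converged: bool

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coefficients


def fit_mm_regression(
    design,
    response,
    efficiency: float = 0.95,
    n_subsets: int = 50,
    n_keep: int = 5,
    max_iter: int = 200,
    tol: float = 1e-9,
    seed: int = 0,
) -> MMRegressionResult:
    """MM-estimate of a linear regression.

    Parameters
    ----------
    design
        n x p design matrix (include an intercept column if wanted).
    response
        Length-n response vector.
    efficiency
        Asymptotic efficiency of the M-step at the normal model,
        in (0.5, 1).
    n_subsets
        Number of random elemental p-subsets for the fast-S stage.

    The S-stage minimizes the bisquare M-scale over candidate fits from
    random elemental subsets (each refined by a few IRWLS steps); the
    M-stage then runs IRWLS at the fixed S-scale with the
    efficiency-tuned bisquare.  Standard errors use the usual MM sandwich
    formula.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    n, p = X.shape
    if n < p + 5:
        raise ValueError("need at least p + 5 observations")
    c1 = bisquare_tuning_constant(efficiency)
    c0 = BISQUARE_C_50_BREAKDOWN
    b = 0.5 * _rho_bisquare(np.array([c0]), c0)[0]  # = 0.5 * c0^2 / 6

    rng = np.random.default_rng(seed)

    # --- S stage: candidate fits from elemental subsets ------------------
    candidates = []
    ls_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    candidates.append(ls_beta)
    for _ in range(n_subsets):
        idx = rng.choice(n, size=p, replace=False)
        try:
            beta = np.linalg.solve(X[idx], y[idx])
        except np.linalg.LinAlgError:
            continue
        if np.isfinite(beta).all():
            candidates.append(beta)

    scored = []
    for beta in candidates:
        r = y - X @ beta
        s = _m_scale(r, c0, b)
        scored.append((s, beta))
    scored.sort(key=lambda t: t[0])

    best_scale, best_beta = np.inf, scored[0][1]
    for s, beta in scored[:n_keep]:
        if s == 0.0:
            best_scale, best_beta = 0.0, beta
            break
        bb = beta.copy()
        ss = s
        for _ in range(20):
            bb, _, _ = _irwls(X, y, bb, ss, c0, 1e-7, 1)
            ss = _m_scale(y - X @ bb, c0, b, s0=ss)
        if ss < best_scale:
            best_scale, best_beta = ss, bb

    if best_scale == 0.0:
        # exact fit: residual scale zero, coefficients from the exact subset
        r = y - X @ best_beta
        w = np.ones(n)
        se = np.zeros(p)
        return MMRegressionResult(
            coefficients=best_beta,
            scale=0.0,
            weights=w,
            cov=np.zeros((p, p)),
            se=se,
            efficiency=efficiency,
            n_iter=0,
            converged=True,
        )

    # --- M stage at fixed S-scale ----------------------------------------
    beta, n_iter, converged = _irwls(X, y, best_beta, best_scale, c1, tol, max_iter)
    if not converged:
        raise ConvergenceError(
            f"MM M-step did not converge in {max_iter} iterations",
            last_coefficients=beta,
        )

    r = y - X @ beta
    u = r / best_scale
    w = _weight_bisquare(u, c1)
    psi = _psi_bisquare(u, c1)
    psi_prime_mean = float(
        np.mean((1 - np.clip(u / c1, -1, 1) ** 2) * (1 - 5 * np.clip(u / c1, -1, 1) ** 2) * (np.abs(u) <= c1))
    )
    kappa = float(np.mean(psi**2)) / max(psi_prime_mean**2, 1e-12)
    xtx_inv = np.linalg.pinv(X.T @ X / n)
    cov = (best_scale**2) * kappa * xtx_inv / n
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    return MMRegressionResult(
        coefficients=beta,
        scale=float(best_scale),
        weights=w,
        cov=cov,
        se=se,
        efficiency=efficiency,
        n_iter=n_iter,
        converged=converged,
    )
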