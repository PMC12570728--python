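"""Sure independence screening (SIS) of CpG probes.

Reduces the probe dimension from thousands to a moderate size d (default
ceil(2 n / ln n)) by keeping the probes most associated with the
continuous outcome.  The per-probe statistic is the absolute t statistic
of the probe in a linear model of the outcome on probe + adjustment
covariates, computed for all probes at once by residualizing both sides
on the covariates (Frisch-Waugh), so the ranking equals brute-force
per-probe regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScreenResult", "default_screen_size", "sis_screen"]


@dataclass
class ScreenResult:
    """Probes surviving the screen, ordered by decreasing |t|."""

    kept_probe_ids: list[str]
    marginal_stat: dict[str, float]
    d: int


def default_screen_size(n: int) -> int:
    """Conventional SIS size d = ceil(2 n / ln n)."""
    return int(np.ceil(2.0 * n / np.log(n)))


def sis_screen(
    M,
    target: np.ndarray,
    covariates: np.ndarray | None = None,
    d: int | None = None,
) -> ScreenResult:
    """Keep the top-d probes by partial association with the target.

    Parameters
    ----------
    M
        :class:`~medipipe.datatypes.MethylationMatrix` or a samples x
        probes DataFrame/array with probe names as columns.
    target
        Continuous response vector (the standardized birth weight).
    covariates
        Numeric adjustment matrix (exposure, maternal covariates, cell
        proportions).  ``None`` screens on the raw marginal correlation.
    d
        Screening size; defaults to ceil(2 n / ln n).  Values above the
        probe count keep every probe.

    A constant probe gets statistic 0 (ranked last), never an error.
    """
    beta = M.beta if hasattr(M, "beta") else M
    probe_ids = list(beta.columns) if hasattr(beta, "columns") else [
        f"p{i}" for i in range(np.asarray(beta).shape[1])
    ]
    X = np.asarray(beta, dtype=float)
    y = np.asarray(target, dtype=float)
    n, p = X.shape
    if y.size != n:
        raise ValueError("target length does not match sample count")
    if d is None:
        d = default_screen_size(n)
    if d < 1:
        raise ValueError("screening size d must be >= 1")

    if covariates is None or np.size(covariates) == 0:
        Z = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        Z = np.column_stack([np.ones(n), covariates])
    k = Z.shape[1]

    q, _ = np.linalg.qr(Z)
    y_res = y - q @ (q.T @ y)
    X_res = X - q @ (q.T @ X)

    sxx = np.einsum("ij,ij->j", X_res, X_res)
    # a probe that is constant, or perfectly explained by the covariates,
    # has no usable residual variation: statistic 0, never a failure
    col_scale = np.maximum(X.var(axis=0), np.mean(X * X, axis=0) * 1e-12)
    sxx = np.where(sxx > n * col_scale * 1e-12, sxx, 0.0)
    sxy = X_res.T @ y_res
    syy = float(y_res @ y_res)
    dof = n - k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = syy - slope * sxy
        sigma2 = rss / dof
        tstat = np.where(
            (sxx > 0) & (sigma2 > 0),
            np.abs(slope) / np.sqrt(np.where(sigma2 > 0, sigma2, 1.0) / np.where(sxx > 0, sxx, 1.0)),
            0.0,
        )
    tstat = np.nan_to_num(tstat, nan=0.0, posinf=np.finfo(float).max)

    # stable ordering: decreasing |t|, ties broken by probe position
    order = np.lexsort((np.arange(p), -tstat))
    keep = order[: min(d, p)]
    return ScreenResult(
        kept_probe_ids=[probe_ids[i] for i in keep],
        marginal_stat={probe_ids[i]: float(tstat[i]) for i in range(p)},
        d=int(d),
    )
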