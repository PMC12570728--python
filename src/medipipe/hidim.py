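"""Step 2: high-dimensional mediator selection.

Three two-stage algorithms share a common skeleton — sure independence
screening (SIS) of the probes against the outcome, a penalized outcome
model over the screened probes, per-probe exposure->mediator regressions,
and a joint-significance test (max of the two path p-values) with FDR
control:

* HDMA  — de-biased LASSO outcome model, Benjamini-Hochberg ("uniform")
  FDR on the max-p statistic;
* HIMA  — MCP outcome model with OLS refit, Benjamini-Hochberg FDR;
* HIMA2 — de-biased LASSO outcome model, composite-null ("mixture") FDR
  that estimates the three null-component proportions and is never more
  conservative than BH on the same input.

Per-mediator contributions alpha_a * beta_m are summed into the global
indirect effect; the direct effect is the total effect (covariate-
adjusted exposure->outcome OLS slope on the same complete cases) minus
the global indirect effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .penalized import fit_debiased_lasso, fit_mcp
from .screening import ScreenResult, default_screen_size, sis_screen

__all__ = [
    "MediationCandidate",
    "MethodResult",
    "fit_mediator_models",
    "joint_significance",
    "adjust_fdr_bh",
    "adjust_fdr_mixture",
    "run_hdma",
    "run_hima",
    "run_hima2",
    "run_all_methods",
    "pool_candidates",
]

logger = logging.getLogger(__name__)


@dataclass
class MediationCandidate:
    """One CpG probe's mediation evidence under one selection method."""

    probe_id: str
    alpha_a: float
    beta_m: float
    contribution: float
    p_alpha: float
    p_beta: float
    p_joint: float
    p_fdr: float
    method: str


@dataclass
class MethodResult:
    """Output of one high-dimensional selection method."""

    method: str
    selected: list[MediationCandidate]    # post-penalty, pre-FDR
    candidates: list[MediationCandidate]  # p_fdr < threshold
    global_indirect: float
    direct_effect: float
    total_effect: float
    screen: ScreenResult = field(repr=False, default=None)  # type: ignore[assignment]

    def candidate_ids(self) -> list[str]:
        return [c.probe_id for c in self.candidates]

    def selected_ids(self) -> list[str]:
        return [c.probe_id for c in self.selected]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "probe_id": c.probe_id,
                "alpha_a": c.alpha_a,
                "beta_m": c.beta_m,
                "contribution": c.contribution,
                "p_alpha": c.p_alpha,
                "p_beta": c.p_beta,
                "p_joint": c.p_joint,
                "p_fdr": c.p_fdr,
                "method": c.method,
                "candidate": c in self.candidates,
            }
            for c in self.selected
        ]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# component operations
# --------------------------------------------------------------------------

def fit_mediator_models(
    M_screened,
    exposure,
    covariates=None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-probe OLS of mediator on exposure (+ covariates).

    Fits probe ~ exposure + covariates for every screened probe at once
    (the design is shared, so all fits reduce to one least-squares solve)
    and returns the exposure slope alpha_a with its t-test p-value.
    """
    beta = M_screened.beta if hasattr(M_screened, "beta") else M_screened
    probe_ids = list(beta.columns) if hasattr(beta, "columns") else [
        f"p{i}" for i in range(np.asarray(beta).shape[1])
    ]
    M = np.asarray(beta, dtype=float)
    if M.shape[1] == 0:
        raise ValueError("screened probe set is empty")
    x = np.asarray(exposure, dtype=float)
    n = x.size

    cols = [np.ones(n), x]
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    X = np.column_stack(cols)
    # drop collinear covariate columns (never the exposure) with a warning
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10 * np.abs(r[0, 0])
        keep[:2] = True
        dropped = np.flatnonzero(~keep)
        logger.warning("dropping %d collinear covariate column(s)", dropped.size)
        X = X[:, keep]
    k = X.shape[1]

    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    resid = M - X @ coef
    dof = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    var_slope = sigma2 * xtx_inv[1, 1]
    alpha_a = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(var_slope > 0, alpha_a / np.sqrt(np.where(var_slope > 0, var_slope, 1.0)), 0.0)
    p_alpha = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return alpha_a, p_alpha, probe_ids


def joint_significance(p_alpha, p_beta) -> np.ndarray:
    """Joint-significance (max-p) mediation p-value, elementwise."""
    pa = np.asarray(p_alpha, dtype=float)
    pb = np.asarray(p_beta, dtype=float)
    for name, v in (("p_alpha", pa), ("p_beta", pb)):
        if ((v < 0) | (v > 1)).any() or np.isnan(v).any():
            raise ValueError(f"{name} contains values outside [0, 1]")
    return np.maximum(pa, pb)


def adjust_fdr_bh(p_joint) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_joint, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_fdr_mixture(
    p_alpha,
    p_beta,
    threshold: float = 0.05,
    lambda_threshold: float = 0.5,
) -> tuple[np.ndarray, dict, np.ndarray]:
    """Composite-null ("mixture") FDR for the max-p statistic.

    The null of no mediation is composite: the exposure->mediator path is
    null, the mediator->outcome path is null, or both.  Null proportions
    are estimated per path by a Storey-type estimator at
    ``lambda_threshold`` and combined multiplicatively; the estimated
    FDR at cutoff t is ``[(pi01 + pi10) t + pi00 t^2] m / R(t)``, turned
    into monotone q-values.  Because the bracket is at most t, the
    q-values never exceed BH q-values on max-p, so the procedure never
    flags fewer tests than BH at the same threshold.

    Returns (flags, null-proportion estimates, q-values).
    """
    pa = np.asarray(p_alpha, dtype=float)
    pb = np.asarray(p_beta, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("p_alpha and p_beta must have equal length")
    m = pa.size
    if m == 0:
        return np.zeros(0, dtype=bool), {}, np.zeros(0)

    lam = lambda_threshold
    pi0_a = min(1.0, (pa > lam).sum() / ((1.0 - lam) * m))
    pi0_b = min(1.0, (pb > lam).sum() / ((1.0 - lam) * m))
    pi00 = pi0_a * pi0_b
    pi01 = pi0_a * (1.0 - pi0_b)  # alpha path null, beta path active
    pi10 = (1.0 - pi0_a) * pi0_b  # beta path null, alpha path active
    props = {"pi00": pi00, "pi01": pi01, "pi10": pi10}

    p_max = np.maximum(pa, pb)
    order = np.argsort(p_max, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    t = p_max
    fdr = ((pi01 + pi10) * t + pi00 * t**2) * m / np.maximum(ranks, 1)
    # enforce monotone q-values (step-up)
    q = np.empty(m)
    sorted_fdr = fdr[order]
    q_sorted = np.minimum.accumulate(sorted_fdr[::-1])[::-1]
    q[order] = np.minimum(q_sorted, 1.0)
    flags = q < threshold
    return flags, props, q


# --------------------------------------------------------------------------
# method drivers
# --------------------------------------------------------------------------

def _total_effect(y, exposure, covariates) -> float:
    n = y.size
    cols = [np.ones(n), np.asarray(exposure, dtype=float)]
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, np.asarray(y, dtype=float), rcond=None)
    return float(coef[1])


@dataclass
class _SharedFits:
    """SIS + both penalized fits + alpha-path fits, computed once."""

    screen: ScreenResult
    probe_ids: list[str]
    alpha_a: np.ndarray
    p_alpha: np.ndarray
    dl_beta: np.ndarray
    dl_p: np.ndarray
    dl_selected: np.ndarray
    mcp_beta: np.ndarray
    mcp_p: np.ndarray
    mcp_selected: np.ndarray
    total_effect: float


def _compute_shared(
    M, exposure, Y, covariates, d, seed, gamma, methods,
) -> _SharedFits:
    beta = M.beta if hasattr(M, "beta") else M
    if not hasattr(beta, "columns"):
        arr = np.asarray(beta, dtype=float)
        beta = pd.DataFrame(arr, columns=[f"p{i}" for i in range(arr.shape[1])])
    y = np.asarray(Y, dtype=float)
    x = np.asarray(exposure, dtype=float)
    n = y.size
    if d is None:
        d = default_screen_size(n)

    C = None
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]

    screen_cov = np.column_stack([x] + ([C] if C is not None else []))
    screen = sis_screen(beta, y, covariates=screen_cov, d=d)
    M_scr = beta[screen.kept_probe_ids]

    alpha_a, p_alpha, probe_ids = fit_mediator_models(M_scr, x, C)

    need_dl = bool({"hdma", "hima2"} & methods)
    need_mcp = "hima" in methods
    p = len(probe_ids)
    dl_beta, dl_p = np.full(p, np.nan), np.full(p, np.nan)
    dl_selected = np.zeros(p, dtype=bool)
    mcp_beta, mcp_p = np.full(p, np.nan), np.full(p, np.nan)
    mcp_selected = np.zeros(p, dtype=bool)
    if need_dl:
        dl = fit_debiased_lasso(y, M_scr, exposure=x, covariates=C, seed=seed)
        dl_beta, dl_p, dl_selected = dl.beta, dl.p, dl.selected
    if need_mcp:
        mc = fit_mcp(y, M_scr, exposure=x, covariates=C, gamma=gamma, seed=seed)
        mcp_beta, mcp_p, mcp_selected = mc.beta, mc.p, mc.selected

    return _SharedFits(
        screen=screen,
        probe_ids=probe_ids,
        alpha_a=alpha_a,
        p_alpha=p_alpha,
        dl_beta=dl_beta,
        dl_p=dl_p,
        dl_selected=dl_selected,
        mcp_beta=mcp_beta,
        mcp_p=mcp_p,
        mcp_selected=mcp_selected,
        total_effect=_total_effect(y, x, C),
    )


def _assemble(
    method: str,
    shared: _SharedFits,
    beta_m: np.ndarray,
    p_beta: np.ndarray,
    support: np.ndarray,
    fdr_threshold: float,
) -> MethodResult:
    idx = np.flatnonzero(support)
    pa = shared.p_alpha[idx]
    pb = p_beta[idx]
    pj = joint_significance(pa, pb)
    if method == "hima2":
        flags, _props, q = adjust_fdr_mixture(pa, pb, threshold=fdr_threshold)
    else:
        q = adjust_fdr_bh(pj)
        flags = q < fdr_threshold

    selected, candidates = [], []
    for pos, j in enumerate(idx):
        cand = MediationCandidate(
            probe_id=shared.probe_ids[j],
            alpha_a=float(shared.alpha_a[j]),
            beta_m=float(beta_m[j]),
            contribution=float(shared.alpha_a[j] * beta_m[j]),
            p_alpha=float(pa[pos]),
            p_beta=float(pb[pos]),
            p_joint=float(pj[pos]),
            p_fdr=float(q[pos]),
            method=method.upper(),
        )
        selected.append(cand)
        if flags[pos]:
            candidates.append(cand)

    global_indirect = float(sum(c.contribution for c in selected))
    total = shared.total_effect
    return MethodResult(
        method=method.upper(),
        selected=selected,
        candidates=candidates,
        global_indirect=global_indirect,
        direct_effect=total - global_indirect,
        total_effect=total,
        screen=shared.screen,
    )


def run_all_methods(
    M,
    exposure,
    Y,
    covariates=None,
    d: int | None = None,
    fdr_threshold: float = 0.05,
    seed: int = 0,
    gamma: float = 3.0,
    methods: tuple[str, ...] = ("hdma", "hima", "hima2"),
) -> dict[str, MethodResult]:
    """Run the requested selection methods, sharing common fits.

    HDMA and HIMA2 share the SIS screen and the de-biased LASSO outcome
    model (they differ only in the FDR step); HIMA shares the screen and
    the per-probe exposure models.  Results are identical to running each
    method alone with the same seed.
    """
    methods = tuple(m.lower() for m in methods)
    unknown = set(methods) - {"hdma", "hima", "hima2"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    shared = _compute_shared(M, exposure, Y, covariates, d, seed, gamma, set(methods))
    out: dict[str, MethodResult] = {}
    for m in methods:
        if m == "hima":
            out[m] = _assemble(
                m, shared, shared.mcp_beta, shared.mcp_p, shared.mcp_selected,
                fdr_threshold,
            )
        else:
            out[m] = _assemble(
                m, shared, shared.dl_beta, shared.dl_p, shared.dl_selected,
                fdr_threshold,
            )
    return out


def run_hdma(M, exposure, Y, covariates=None, d=None, fdr_threshold=0.05, seed=0):
    """SIS -> de-biased LASSO -> joint significance -> BH FDR."""
    return run_all_methods(
        M, exposure, Y, covariates, d, fdr_threshold, seed, methods=("hdma",)
    )["hdma"]


def run_hima(M, exposure, Y, covariates=None, d=None, fdr_threshold=0.05, seed=0, gamma=3.0):
    """SIS -> MCP (OLS refit) -> joint significance -> BH FDR."""
    return run_all_methods(
        M, exposure, Y, covariates, d, fdr_threshold, seed, gamma=gamma,
        methods=("hima",),
    )["hima"]


def run_hima2(M, exposure, Y, covariates=None, d=None, fdr_threshold=0.05, seed=0):
    """SIS -> de-biased LASSO -> joint significance -> mixture FDR."""
    return run_all_methods(
        M, exposure, Y, covariates, d, fdr_threshold, seed, methods=("hima2",)
    )["hima2"]


def pool_candidates(
    results,
    threshold: float = 0.05,
) -> tuple[list[str], dict[str, list[str]]]:
    """Union of per-method candidate sets with per-method provenance.

    Accepts :class:`MethodResult` objects or plain (method, probe-id list)
    pairs.  Returns the pooled probe ids (stable order of first
    appearance) and a probe -> methods provenance map.
    """
    pooled: list[str] = []
    provenance: dict[str, list[str]] = {}
    for res in results:
        if isinstance(res, MethodResult):
            method = res.method
            ids = [c.probe_id for c in res.candidates if c.p_fdr < threshold]
        else:
            method, ids = res
        for probe in ids:
            if probe not in provenance:
                provenance[probe] = []
                pooled.append(probe)
            provenance[probe].append(method)
    return pooled, provenance
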