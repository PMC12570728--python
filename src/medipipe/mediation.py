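"""Step 3: classical low-dimensional causal mediation.

Single-, serial- (up to three mediators) and parallel-mediator models on
the pooled candidate CpGs, estimated either by OLS or by robust
MM-regression, with case-resampling percentile-bootstrap confidence
intervals for every indirect pathway.

Indirect effects are products of structural-equation coefficients; in a
serial model with k mediators every non-empty ordered subset of the chain
is a pathway (2^k - 1 of them).  The total indirect effect is the sum of
pathway estimates and the total effect is direct + total indirect, so the
decomposition identities hold exactly on every fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .robust import fit_mm_regression

__all__ = [
    "MediationModelSpec",
    "PathwayEffect",
    "EffectDecomposition",
    "enumerate_serial_pathways",
    "estimate_paths",
    "bootstrap_mediation",
    "select_serial_mediators",
    "accounting_totals",
]

logger = logging.getLogger(__name__)

MAX_SERIAL_MEDIATORS = 3


class UnsupportedTopologyError(ValueError):
    """Serial models support at most three mediators."""


@dataclass
class MediationModelSpec:
    """Configuration of one classical mediation model."""

    exposure_name: str
    mediator_ids: list[str]
    topology: str = "single"  # single | serial | parallel
    estimator: str = "ols"    # ols | robust
    n_boot: int = 5000
    ci_level: float = 0.95
    covariate_names: list[str] = field(default_factory=list)
    outcome_name: str = "z_birthweight"
    efficiency: float = 0.95
    mm_subsets: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in {"single", "serial", "parallel"}:
            raise ValueError(f"unknown topology {self.topology!r}")
        k = len(self.mediator_ids)
        if self.topology == "single" and k != 1:
            raise ValueError("single topology requires exactly one mediator")
        if self.topology == "serial":
            if k < 2:
                raise ValueError("serial topology requires at least two mediators")
            if k > MAX_SERIAL_MEDIATORS:
                raise UnsupportedTopologyError(
                    f"serial models support at most {MAX_SERIAL_MEDIATORS} mediators"
                )
        if self.estimator not in {"ols", "robust"}:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.n_boot < 1000:
            logger.info(
                "n_boot=%d is below the 1000 recommended for reported CIs",
                self.n_boot,
            )


@dataclass
class PathwayEffect:
    label: str
    mediator_chain: tuple[str, ...]
    estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    significant: bool | None = None


@dataclass
class EffectDecomposition:
    pathways: list[PathwayEffect]
    total_indirect: float
    total_indirect_ci: tuple[float, float] | None
    direct: tuple[float, float, float]   # estimate, se, p
    total: tuple[float, float, float]    # estimate, se, p
    spec: MediationModelSpec | None = None
    n_used: int = 0
    n_boot_failures: int = 0

    def pathway(self, chain) -> PathwayEffect:
        chain = tuple(chain)
        for pw in self.pathways:
            if pw.mediator_chain == chain:
                return pw
        raise KeyError(f"no pathway {chain}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pathway": pw.label,
                "estimate": pw.estimate,
                "ci_low": pw.ci_low,
                "ci_high": pw.ci_high,
                "significant": pw.significant,
            }
            for pw in self.pathways
        ]
        rows.append(
            {
                "pathway": "Total indirect",
                "estimate": self.total_indirect,
                "ci_low": self.total_indirect_ci[0] if self.total_indirect_ci else np.nan,
                "ci_high": self.total_indirect_ci[1] if self.total_indirect_ci else np.nan,
                "significant": (
                    not (self.total_indirect_ci[0] <= 0.0 <= self.total_indirect_ci[1])
                    if self.total_indirect_ci
                    else None
                ),
            }
        )
        return pd.DataFrame(rows)


def enumerate_serial_pathways(k: int) -> list[tuple[int, ...]]:
    """All indirect pathways of a serial model with k ordered mediators.

    Returns index chains (0-based into the serial order): singletons
    first, then pairs in lexicographic order, then the full chain —
    2^k - 1 pathways in total.  k is capped at three.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > MAX_SERIAL_MEDIATORS:
        raise UnsupportedTopologyError(
            f"serial models support at most {MAX_SERIAL_MEDIATORS} mediators"
        )
    chains: list[tuple[int, ...]] = []
    for size in range(1, k + 1):
        from itertools import combinations

        chains.extend(combinations(range(k), size))
    return chains


def _fit_equation(design: np.ndarray, y: np.ndarray, spec: MediationModelSpec, seed: int):
    """Fit one structural equation; returns (coefficients, se, p)."""
    if spec.estimator == "robust":
        res = fit_mm_regression(
            design, y, efficiency=spec.efficiency, n_subsets=spec.mm_subsets,
            seed=seed,
        )
        coef, se = res.coefficients, res.se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.inf * np.sign(coef))
        p = 2.0 * stats.norm.sf(np.abs(z))
        return coef, se, p
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = max(design.shape[0] - design.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.inf * np.sign(coef))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return coef, se, p


def _point_estimates(
    Mmat: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    C: np.ndarray | None,
    spec: MediationModelSpec,
    seed: int,
):
    """Fit all structural equations; return pathway products and effects."""
    n, k = Mmat.shape
    ones = np.ones(n)
    Cpart = [C] if C is not None and C.size else []

    a = np.zeros(k)                 # X -> M_j in M_j's equation
    d = np.zeros((k, k))            # M_i -> M_j (serial only, i < j)
    for j in range(k):
        if spec.topology == "serial":
            prior = [Mmat[:, :j]] if j > 0 else []
        else:
            prior = []
        design = np.column_stack([ones, x, *prior, *Cpart])
        coef, _, _ = _fit_equation(design, Mmat[:, j], spec, seed)
        a[j] = coef[1]
        if spec.topology == "serial" and j > 0:
            d[:j, j] = coef[2 : 2 + j]

    design_y = np.column_stack([ones, x, Mmat, *Cpart])
    coef_y, se_y, p_y = _fit_equation(design_y, y, spec, seed + 1)
    direct_est, direct_se, direct_p = coef_y[1], se_y[1], p_y[1]
    b = coef_y[2 : 2 + k]

    if spec.topology in {"single", "parallel"}:
        chains = [(j,) for j in range(k)]
    else:
        chains = enumerate_serial_pathways(k)
    estimates = []
    for chain in chains:
        prod = a[chain[0]]
        for prev, nxt in zip(chain, chain[1:]):
            prod *= d[prev, nxt]
        prod *= b[chain[-1]]
        estimates.append(prod)

    # total-effect regression for its own se / p (sum convention for estimate)
    design_t = np.column_stack([ones, x, *Cpart])
    coef_t, se_t, p_t = _fit_equation(design_t, y, spec, seed + 2)
    return (
        chains,
        np.asarray(estimates),
        (float(direct_est), float(direct_se), float(direct_p)),
        (float(se_t[1]), float(p_t[1])),
    )


def _prepare(M_sub, exposure, Y, covariates, spec):
    beta = M_sub.beta if hasattr(M_sub, "beta") else M_sub
    if hasattr(beta, "columns"):
        missing = [m for m in spec.mediator_ids if m not in beta.columns]
        if missing:
            raise KeyError(f"mediators absent from matrix: {missing}")
        Mmat = np.asarray(beta[spec.mediator_ids], dtype=float)
    else:
        Mmat = np.asarray(beta, dtype=float)
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(Y, dtype=float)
    C = None
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    # listwise deletion
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(Mmat).all(axis=1)
    if C is not None:
        ok &= np.isfinite(C).all(axis=1)
    Mmat, x, y = Mmat[ok], x[ok], y[ok]
    if C is not None:
        C = C[ok]
        # drop covariate columns that are collinear with [1, x] or each other
        base = np.column_stack([np.ones(len(x)), x])
        keep = []
        for j in range(C.shape[1]):
            trial = np.column_stack([base, C[:, keep + [j]]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                keep.append(j)
        if len(keep) < C.shape[1]:
            logger.warning(
                "dropping %d collinear covariate column(s)", C.shape[1] - len(keep)
            )
        C = C[:, keep] if keep else None
    return Mmat, x, y, C


def _labels(spec: MediationModelSpec, chains) -> list[tuple[str, tuple[str, ...]]]:
    out = []
    for chain in chains:
        meds = tuple(spec.mediator_ids[i] for i in chain)
        label = " -> ".join([spec.exposure_name, *meds, spec.outcome_name])
        out.append((label, meds))
    return out


def estimate_paths(
    M_sub,
    exposure,
    Y,
    covariates,
    spec: MediationModelSpec,
) -> EffectDecomposition:
    """Point decomposition of one mediation model (no bootstrap CIs)."""
    Mmat, x, y, C = _prepare(M_sub, exposure, Y, covariates, spec)
    chains, estimates, direct, total_sep = _point_estimates(
        Mmat, x, y, C, spec, spec.seed
    )
    total_indirect = float(estimates.sum())
    total_est = direct[0] + total_indirect
    pathways = [
        PathwayEffect(label=lab, mediator_chain=meds, estimate=float(est))
        for (lab, meds), est in zip(_labels(spec, chains), estimates)
    ]
    return EffectDecomposition(
        pathways=pathways,
        total_indirect=total_indirect,
        total_indirect_ci=None,
        direct=direct,
        total=(float(total_est), total_sep[0], total_sep[1]),
        spec=spec,
        n_used=len(y),
    )


def bootstrap_mediation(
    M_sub,
    exposure,
    Y,
    covariates,
    spec: MediationModelSpec,
    return_draws: bool = False,
):
    """Case-resampling percentile bootstrap of a mediation model.

    Whole rows are resampled with replacement ``spec.n_boot`` times; the
    percentile interval at ``spec.ci_level`` is reported for every
    pathway and for the total indirect effect.  Direct- and total-effect
    inference (se, p) comes from the estimator's asymptotics on the
    original sample.  A failed refit (singular resample, non-convergence)
    is redrawn and counted; more than 10% failures aborts.
    """
    Mmat, x, y, C = _prepare(M_sub, exposure, Y, covariates, spec)
    n = len(y)
    point = estimate_paths(M_sub, exposure, Y, covariates, spec)
    chains = [tuple(spec.mediator_ids.index(m) for m in pw.mediator_chain)
              for pw in point.pathways]

    rng = np.random.default_rng(spec.seed)
    draws = np.empty((spec.n_boot, len(chains)))
    failures = 0
    max_failures = max(10, int(0.1 * spec.n_boot))
    i = 0
    while i < spec.n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            _, est, _, _ = _point_estimates(
                Mmat[idx], x[idx], y[idx], (C[idx] if C is not None else None),
                spec, spec.seed + 1000 + i,
            )
        except (np.linalg.LinAlgError, ValueError, RuntimeError):
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"more than 10% of bootstrap refits failed ({failures})"
                )
            continue
        draws[i] = est
        i += 1
    if failures:
        logger.warning("%d bootstrap resamples redrawn after refit failure", failures)

    lo_q = (1.0 - spec.ci_level) / 2.0
    hi_q = 1.0 - lo_q
    ci_low = np.quantile(draws, lo_q, axis=0)
    ci_high = np.quantile(draws, hi_q, axis=0)
    for j, pw in enumerate(point.pathways):
        pw.ci_low = float(ci_low[j])
        pw.ci_high = float(ci_high[j])
        pw.significant = not (pw.ci_low <= 0.0 <= pw.ci_high)
        if not pw.ci_low <= pw.estimate <= pw.ci_high:
            logger.warning(
                "percentile CI for %s does not contain the point estimate", pw.label
            )

    ti_draws = draws.sum(axis=1)
    point.total_indirect_ci = (
        float(np.quantile(ti_draws, lo_q)),
        float(np.quantile(ti_draws, hi_q)),
    )
    point.n_boot_failures = failures
    if return_draws:
        return point, draws
    return point


def select_serial_mediators(
    single_results: list[EffectDecomposition],
    k: int,
) -> list[str]:
    """Rank single-model results and return the top-k mediator ids.

    Default ranking: bootstrap-significant indirect effects first, then
    decreasing |indirect estimate|, ties broken by probe id.  Returns all
    available mediators (with a warning) when fewer than k exist.
    """
    if k > MAX_SERIAL_MEDIATORS:
        raise UnsupportedTopologyError(
            f"serial models support at most {MAX_SERIAL_MEDIATORS} mediators"
        )
    if k <= 0:
        return []
    entries = []
    for res in single_results:
        pw = res.pathways[0]
        probe = pw.mediator_chain[0]
        sig = bool(pw.significant) if pw.significant is not None else False
        entries.append((0 if sig else 1, -abs(pw.estimate), probe))
    entries.sort()
    ranked = [probe for _, _, probe in entries]
    if len(ranked) < k:
        logger.warning(
            "only %d single-mediator results available, requested %d", len(ranked), k
        )
        return ranked
    return ranked[:k]


def accounting_totals(
    pathway_estimates,
    direct_estimate: float,
) -> tuple[float, float]:
    """Decomposition accounting: (total indirect, total effect).

    The total indirect effect is the sum of the pathway estimates and the
    total effect is direct + total indirect — the additive identities
    every printed decomposition must satisfy.
    """
    total_indirect = float(np.sum(np.asarray(pathway_estimates, dtype=float)))
    return total_indirect, float(direct_estimate) + total_indirect
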