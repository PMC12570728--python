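"""Synthetic cohort generator.

Emulates a mother-child birth cohort in which a continuous maternal
exposure (by default gestational weight gain, GWG, in kg) influences the
child's standardized birth weight both directly and through a handful of
planted cord-blood CpG mediators, against a background of correlated null
probes, confounding covariates, cord-blood cell composition and
missingness.  Every downstream stage of the pipeline is testable against
the returned :class:`~medipipe.datatypes.CohortTruth`.

Generative model
----------------
Exposure:   X_i ~ N(mu_x, sd_x), default mu=15.2, sd=5.6 (GWG, kg).
Mediators:  on the logit scale, L_ij = logit(m0_j) + a_j (X_i - mu_x)
            + covariate terms + eps, with a_j = alpha_a_j / (m0_j (1 - m0_j))
            so that the local slope of beta on X equals the requested
            alpha_a_j on the beta scale; beta = expit(L) clipped to
            [1e-6, 1 - 1e-6].
Null probes: block-correlated logit-normal noise (default block size 10).
Outcome:    Y_i = mu_y + c (X_i - mu_x) + sum_j beta_m_j (M_ij - mean_j)
            + covariate terms + N(0, noise_sd_outcome), default mu_y = -0.42.

Because the expit squashes tails, the realized beta-scale slope differs
slightly from the nominal alpha_a; the generator therefore stores the
realized empirical slope (covariate-adjusted OLS of each true mediator on
X) in ``CohortTruth.alpha_a`` and the nominal value separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import CohortTruth, MethylationMatrix

__all__ = [
    "SimulationConfig",
    "CELL_TYPE_NAMES",
    "simulate_cohort",
    "simulate_cell_proportions",
    "inject_missingness",
]

#: Cord-blood leukocyte compartments used for the default composition.
CELL_TYPE_NAMES = ["Bcell", "CD4T", "CD8T", "Gran", "Mono", "NK"]

#: Table-1-like category frequencies for the categorical covariates.
EDUCATION_LEVELS = ["Primary", "UpperSecondary", "University"]
EDUCATION_PROBS = [11 / 691, 164 / 691, 516 / 691]
COUNTRY_LEVELS = ["Sweden", "Other"]
COUNTRY_PROBS = [630 / 692, 62 / 692]
SMOKING_LEVELS = ["No", "Yes"]
SMOKING_PROBS = [681 / 683, 2 / 683]


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults target the marginals of the emulated cohort: n = 722,
    exposure (GWG) mean 15.2 sd 5.6 kg, BMI mean 24.5 sd 4.1 kg/m^2,
    z-birthweight mean -0.42, and a strong-signal scenario of three
    planted CpG mediators.
    """

    n_samples: int = 722
    n_probes: int = 1000
    n_true_mediators: int = 3
    alpha_a: np.ndarray = field(default_factory=lambda: np.full(3, 0.002))
    beta_m: np.ndarray = field(default_factory=lambda: np.full(3, 30.0))
    direct_effect: float = 0.02
    exposure_mean: float = 15.2
    exposure_sd: float = 5.6
    outcome_mean: float = -0.42
    bmi_mean: float = 24.5
    bmi_sd: float = 4.1
    covariate_effects: dict = field(default_factory=dict)
    probe_correlation: float = 0.3
    block_size: int = 10
    mediator_base_level: float = 0.5
    null_probe_logit_sd: float = 0.25
    noise_sd_mediator: float = 0.01
    noise_sd_outcome: float = 0.9
    missing_rate: float = 0.0
    missing_columns: tuple = ()
    n_cell_types: int = 6
    cell_concentration: np.ndarray = field(
        default_factory=lambda: np.array([2.0, 12.0, 6.0, 30.0, 4.0, 2.0])
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha_a = np.atleast_1d(np.asarray(self.alpha_a, dtype=float))
        self.beta_m = np.atleast_1d(np.asarray(self.beta_m, dtype=float))
        if self.n_true_mediators > self.n_probes:
            raise ConfigurationError("n_true_mediators exceeds n_probes")
        if self.alpha_a.size != self.n_true_mediators:
            raise ConfigurationError(
                f"alpha_a has length {self.alpha_a.size}, "
                f"expected n_true_mediators={self.n_true_mediators}"
            )
        if self.beta_m.size != self.n_true_mediators:
            raise ConfigurationError(
                f"beta_m has length {self.beta_m.size}, "
                f"expected n_true_mediators={self.n_true_mediators}"
            )
        for name in ("exposure_sd", "noise_sd_mediator", "noise_sd_outcome"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.probe_correlation < 1.0:
            raise ConfigurationError("probe_correlation must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not 0.0 < self.mediator_base_level < 1.0:
            raise ConfigurationError("mediator_base_level must be in (0, 1)")
        self.cell_concentration = np.asarray(self.cell_concentration, dtype=float)
        if self.cell_concentration.size != self.n_cell_types:
            raise ConfigurationError("cell_concentration length != n_cell_types")


def simulate_cell_proportions(
    n_samples: int,
    n_cell_types: int,
    concentration,
    seed: int,
) -> np.ndarray:
    """Draw per-sample cell-type proportions from a Dirichlet distribution.

    Returns an (n_samples, n_cell_types) matrix whose rows sum to one.
    """
    concentration = np.asarray(concentration, dtype=float)
    if concentration.size != n_cell_types:
        raise ValueError("concentration length must equal n_cell_types")
    if (concentration <= 0).any():
        raise ValueError("Dirichlet concentration parameters must be positive")
    rng = np.random.default_rng(seed)
    if n_cell_types == 1:
        return np.ones((n_samples, 1))
    return rng.dirichlet(concentration, size=n_samples)


def inject_missingness(
    pheno: pd.DataFrame,
    rate: float,
    columns,
    seed: int,
) -> pd.DataFrame:
    """Set a random fraction ``rate`` of cells in ``columns`` to missing.

    Missingness is completely at random; non-targeted columns are returned
    untouched.  The input frame is never mutated.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    unknown = [c for c in columns if c not in pheno.columns]
    if unknown:
        raise KeyError(f"unknown phenotype columns: {unknown}")
    out = pheno.copy()
    if rate == 0.0 or not columns:
        return out
    rng = np.random.default_rng(seed)
    for col in columns:
        mask = rng.random(len(out)) < rate
        if mask.any():
            if out[col].dtype.kind in "iu":
                out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out


def _adjusted_slopes(M: np.ndarray, x: np.ndarray, covars: np.ndarray) -> np.ndarray:
    """Realized OLS slopes of each column of M on x, adjusting for covars."""
    n = x.size
    design = np.column_stack([np.ones(n), covars]) if covars.size else np.ones((n, 1))
    # residualize x and M on the adjustment design (Frisch-Waugh)
    q, _ = np.linalg.qr(design)
    x_res = x - q @ (q.T @ x)
    m_res = M - q @ (q.T @ M)
    return (x_res @ m_res) / (x_res @ x_res)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[MethylationMatrix, pd.DataFrame, CohortTruth]:
    """Generate one synthetic cohort.

    Returns the methylation matrix (samples x probes), the phenotype table
    (exposures, outcome, covariates, cell proportions) and the generative
    ground truth.  Identical config (including seed) gives bit-identical
    output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, p, k = cfg.n_samples, cfg.n_probes, cfg.n_true_mediators

    sample_ids = [f"S{i:04d}" for i in range(n)]
    probe_ids = [f"cg{i:08d}" for i in range(p)]
    true_ids = probe_ids[:k]

    # --- covariates -----------------------------------------------------
    maternal_age = rng.normal(29.9, 4.1, size=n)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=EDUCATION_PROBS)
    country = rng.choice(COUNTRY_LEVELS, size=n, p=COUNTRY_PROBS)
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=SMOKING_PROBS)
    bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=n)

    eff = cfg.covariate_effects
    age_c = maternal_age - 29.9
    cov_on_exposure = eff.get("age_on_exposure", 0.0) * age_c
    cov_on_mediator = eff.get("age_on_mediator", 0.0) * age_c
    cov_on_outcome = eff.get("age_on_outcome", 0.0) * age_c
    smoking_ind = (smoking == "Yes").astype(float)
    cov_on_outcome = cov_on_outcome + eff.get("smoking_on_outcome", 0.0) * smoking_ind

    # --- exposure -------------------------------------------------------
    exposure = rng.normal(cfg.exposure_mean, cfg.exposure_sd, size=n) + cov_on_exposure
    x_c = exposure - exposure.mean()

    # --- true mediators (logit-normal with linearized beta-scale slope) --
    m0 = cfg.mediator_base_level
    deriv = m0 * (1.0 - m0)
    logit_noise_sd = cfg.noise_sd_mediator / deriv
    latent = (
        logit(m0)
        + np.outer(x_c, cfg.alpha_a / deriv)
        + (cov_on_mediator / deriv)[:, None]
        + rng.normal(0.0, logit_noise_sd, size=(n, k))
    )
    M_true = np.clip(expit(latent), 1e-6, 1.0 - 1e-6)

    # --- null probes: block-correlated logit-normal ---------------------
    n_null = p - k
    if n_null > 0:
        base = rng.normal(0.0, 1.2, size=n_null)  # spread of probe means
        rho = cfg.probe_correlation
        n_blocks = int(np.ceil(n_null / cfg.block_size))
        block_idx = np.repeat(np.arange(n_blocks), cfg.block_size)[:n_null]
        z_block = rng.normal(0.0, 1.0, size=(n, n_blocks))
        z_ind = rng.normal(0.0, 1.0, size=(n, n_null))
        noise = np.sqrt(rho) * z_block[:, block_idx] + np.sqrt(1.0 - rho) * z_ind
        M_null = np.clip(
            expit(base[None, :] + cfg.null_probe_logit_sd * noise),
            1e-6,
            1.0 - 1e-6,
        )
        beta_values = np.hstack([M_true, M_null])
    else:
        beta_values = M_true

    # --- outcome --------------------------------------------------------
    M_centered = M_true - M_true.mean(axis=0)
    outcome = (
        cfg.outcome_mean
        + cfg.direct_effect * x_c
        + M_centered @ cfg.beta_m
        + cov_on_outcome
        + rng.normal(0.0, cfg.noise_sd_outcome, size=n)
    )

    # --- cell proportions -----------------------------------------------
    cells = simulate_cell_proportions(
        n, cfg.n_cell_types, cfg.cell_concentration, seed=int(rng.integers(2**31))
    )
    cell_names = (
        CELL_TYPE_NAMES[: cfg.n_cell_types]
        if cfg.n_cell_types <= len(CELL_TYPE_NAMES)
        else [f"cell{i}" for i in range(cfg.n_cell_types)]
    )

    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "gwg": exposure,
            "bmi": bmi,
            "z_birthweight": outcome,
            "maternal_age": maternal_age,
            "education": education,
            "country_of_birth": country,
            "smoking": smoking,
        }
    )
    for j, cname in enumerate(cell_names):
        pheno[cname] = cells[:, j]

    if cfg.missing_rate > 0.0 and cfg.missing_columns:
        pheno = inject_missingness(
            pheno,
            cfg.missing_rate,
            list(cfg.missing_columns),
            seed=int(rng.integers(2**31)),
        )

    matrix = MethylationMatrix(
        pd.DataFrame(beta_values, index=sample_ids, columns=probe_ids)
    )

    realized_alpha = (
        _adjusted_slopes(M_true, exposure, age_c[:, None])
        if k
        else np.empty(0)
    )
    truth = CohortTruth(
        true_mediator_ids=true_ids,
        alpha_a=realized_alpha,
        beta_m=cfg.beta_m.copy(),
        direct_effect=cfg.direct_effect,
        expected_total_effect=float(
            cfg.direct_effect + float(realized_alpha @ cfg.beta_m)
        ),
        nominal_alpha_a=cfg.alpha_a.copy(),
    )
    return matrix, pheno, truth
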