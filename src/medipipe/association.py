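"""Step 1: overall exposure-outcome associations.

Unadjusted and covariate-adjusted linear regressions of standardized
birth weight on each maternal exposure, with listwise deletion per model,
plus the supplementary BMI-GWG correlation/subgroup analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AdjustmentSpec",
    "AssociationResult",
    "SubgroupCorrelationResult",
    "InsufficientDataError",
    "DEFAULT_COVARIATES",
    "BMI_COVARIATES",
    "encode_design",
    "fit_exposure_outcome",
    "run_association_screen",
    "correlate_bmi_gwg_subgroups",
]

#: Adjustment set for BMI as the exposure (maternal age, education,
#: country of birth, smoking); every other exposure additionally adjusts
#: for early-pregnancy BMI.
BMI_COVARIATES = ["maternal_age", "education", "country_of_birth", "smoking"]
DEFAULT_COVARIATES = BMI_COVARIATES + ["bmi"]

#: Reference levels for the categorical covariates (most frequent class).
REFERENCE_LEVELS = {
    "education": "University",
    "country_of_birth": "Sweden",
    "smoking": "No",
}

CATEGORICAL_COVARIATES = set(REFERENCE_LEVELS)


class InsufficientDataError(ValueError):
    """Too few complete rows to fit the requested model."""


@dataclass
class AdjustmentSpec:
    """One exposure and its adjustment covariates."""

    exposure_name: str
    covariate_names: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))

    def __post_init__(self) -> None:
        if self.exposure_name in self.covariate_names:
            raise ValueError("exposure cannot appear among its own covariates")


@dataclass
class AssociationResult:
    exposure: str
    beta_unadj: float
    ci_unadj: tuple[float, float]
    p_unadj: float
    beta_adj: float
    ci_adj: tuple[float, float]
    p_adj: float
    n_used: int
    n_used_unadj: int = 0


@dataclass
class SubgroupCorrelationResult:
    subgroup_label: str
    pearson_r: float  # NaN when undefined (n < 3 or zero variance)
    r_pvalue: float
    beta_bmi: float
    p_bmi: float
    beta_gwg: float
    p_gwg: float
    n: int


def encode_design(
    pheno: pd.DataFrame, columns: list[str], add_intercept: bool = True
) -> pd.DataFrame:
    """Build a numeric design matrix, dummy-coding known categoricals.

    Categorical covariates are coded against their reference level
    (education = University, country = Sweden, smoking = No), which moves
    the reference into the intercept and leaves exposure slopes unchanged.
    """
    parts = []
    for col in columns:
        if col in CATEGORICAL_COVARIATES or pheno[col].dtype == object:
            ref = REFERENCE_LEVELS.get(col)
            values = pheno[col]
            levels = [lv for lv in pd.unique(values.dropna()) if lv != ref]
            for lv in sorted(map(str, levels)):
                dummy = (values.astype(str) == lv).astype(float)
                dummy[values.isna()] = np.nan
                parts.append(dummy.rename(f"{col}[{lv}]"))
        else:
            parts.append(pheno[col].astype(float))
    design = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=pheno.index)
    if add_intercept:
        design.insert(0, "const", 1.0)
    return design


def _fit_ols(y: pd.Series, design: pd.DataFrame, term: str):
    model = sm.OLS(y.to_numpy(dtype=float), design.to_numpy(dtype=float))
    res = model.fit()
    idx = list(design.columns).index(term)
    ci = res.conf_int(alpha=0.05)[idx]
    return float(res.params[idx]), (float(ci[0]), float(ci[1])), float(res.pvalues[idx])


def fit_exposure_outcome(
    pheno: pd.DataFrame,
    spec: AdjustmentSpec,
    outcome: str = "z_birthweight",
) -> AssociationResult:
    """Unadjusted and adjusted OLS of the outcome on one exposure.

    Listwise deletion is applied per model: the unadjusted fit drops only
    rows missing the exposure or outcome; the adjusted fit additionally
    drops rows missing any covariate.  95% CIs come from the t
    distribution of each fit.
    """
    exposure = spec.exposure_name
    for col in [exposure, outcome, *spec.covariate_names]:
        if col not in pheno.columns:
            raise KeyError(f"column {col!r} not in phenotype table")

    # unadjusted model
    sub_u = pheno[[exposure, outcome]].dropna()
    design_u = encode_design(sub_u, [exposure])
    n_params_adj = None
    if len(sub_u) < design_u.shape[1] + 2:
        raise InsufficientDataError(
            f"only {len(sub_u)} complete rows for unadjusted model of {exposure}"
        )
    if np.std(sub_u[exposure].to_numpy(dtype=float)) == 0:
        raise ValueError(f"exposure {exposure!r} has zero variance")
    b_u, ci_u, p_u = _fit_ols(sub_u[outcome], design_u, exposure)

    # adjusted model
    cols = [exposure, outcome, *spec.covariate_names]
    sub_a = pheno[cols].dropna()
    design_a = encode_design(sub_a, [exposure, *spec.covariate_names])
    n_params_adj = design_a.shape[1]
    if len(sub_a) < n_params_adj + 2:
        raise InsufficientDataError(
            f"only {len(sub_a)} complete rows for adjusted model of {exposure}"
        )
    # drop constant dummy columns (e.g. a category absent after deletion)
    keep = [
        c
        for c in design_a.columns
        if c == "const" or np.std(design_a[c].to_numpy(dtype=float)) > 0
    ]
    design_a = design_a[keep]
    if np.std(sub_a[exposure].to_numpy(dtype=float)) == 0:
        raise ValueError(f"exposure {exposure!r} has zero variance")
    b_a, ci_a, p_a = _fit_ols(sub_a[outcome], design_a, exposure)

    return AssociationResult(
        exposure=exposure,
        beta_unadj=b_u,
        ci_unadj=ci_u,
        p_unadj=p_u,
        beta_adj=b_a,
        ci_adj=ci_a,
        p_adj=p_a,
        n_used=len(sub_a),
        n_used_unadj=len(sub_u),
    )


def run_association_screen(
    pheno: pd.DataFrame,
    specs: list[AdjustmentSpec],
    alpha: float = 0.05,
    outcome: str = "z_birthweight",
) -> tuple[pd.DataFrame, list[str]]:
    """Fit every exposure's association model and flag significant ones.

    Returns a table with one row per exposure (unadjusted and adjusted
    beta, 95% CI, p, n) and the list of exposures with adjusted p < alpha.
    No multiplicity correction is applied across exposures.
    """
    if not specs:
        raise ValueError("no adjustment specs given")
    names = [s.exposure_name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate exposure names in specs")

    rows, flagged = [], []
    for spec in specs:
        res = fit_exposure_outcome(pheno, spec, outcome=outcome)
        rows.append(
            {
                "exposure": res.exposure,
                "beta_unadj": res.beta_unadj,
                "ci_unadj_low": res.ci_unadj[0],
                "ci_unadj_high": res.ci_unadj[1],
                "p_unadj": res.p_unadj,
                "beta_adj": res.beta_adj,
                "ci_adj_low": res.ci_adj[0],
                "ci_adj_high": res.ci_adj[1],
                "p_adj": res.p_adj,
                "n_used": res.n_used,
            }
        )
        if res.p_adj < alpha:
            flagged.append(res.exposure)
    return pd.DataFrame(rows), flagged


DEFAULT_BMI_CUTS = (18.5, 25.0, 30.0)


def correlate_bmi_gwg_subgroups(
    pheno: pd.DataFrame,
    bmi_cuts: tuple[float, float, float] = DEFAULT_BMI_CUTS,
    outcome: str = "z_birthweight",
    covariates: list[str] | None = None,
) -> list[SubgroupCorrelationResult]:
    """BMI-GWG Pearson correlations and joint regressions by BMI subgroup.

    Subgroups: full cohort, obesity (BMI >= upper cut), obesity+overweight
    (BMI >= middle cut), overweight (middle <= BMI < upper) and normal
    weight (lower <= BMI < middle).  In each subgroup the outcome is also
    regressed jointly on BMI and GWG plus the adjustment covariates.
    Degenerate subgroups (n < 3 or zero variance) report r as NaN.
    """
    lo, mid, hi = bmi_cuts
    if covariates is None:
        covariates = BMI_COVARIATES
    bmi = pheno["bmi"]
    groups = {
        "full": pd.Series(True, index=pheno.index),
        "obesity": bmi >= hi,
        "obesity+overweight": bmi >= mid,
        "overweight": (bmi >= mid) & (bmi < hi),
        "normal": (bmi >= lo) & (bmi < mid),
    }
    out = []
    for label, mask in groups.items():
        sub = pheno[mask.fillna(False)]
        cc = sub[["bmi", "gwg"]].dropna()
        if len(cc) < 3 or cc["bmi"].std() == 0 or cc["gwg"].std() == 0:
            r, rp = float("nan"), float("nan")
        else:
            r, rp = stats.pearsonr(cc["bmi"], cc["gwg"])
        b_bmi = p_bmi = b_gwg = p_gwg = float("nan")
        cols = ["bmi", "gwg", outcome, *covariates]
        sub_m = sub[cols].dropna()
        design = encode_design(sub_m, ["bmi", "gwg", *covariates])
        keep = [
            c
            for c in design.columns
            if c == "const" or np.std(design[c].to_numpy(dtype=float)) > 0
        ]
        design = design[keep]
        if len(sub_m) >= design.shape[1] + 2 and {"bmi", "gwg"} <= set(design.columns):
            res = sm.OLS(
                sub_m[outcome].to_numpy(dtype=float),
                design.to_numpy(dtype=float),
            ).fit()
            cols_d = list(design.columns)
            b_bmi = float(res.params[cols_d.index("bmi")])
            p_bmi = float(res.pvalues[cols_d.index("bmi")])
            b_gwg = float(res.params[cols_d.index("gwg")])
            p_gwg = float(res.pvalues[cols_d.index("gwg")])
        out.append(
            SubgroupCorrelationResult(
                subgroup_label=label,
                pearson_r=float(r),
                r_pvalue=float(rp),
                beta_bmi=b_bmi,
                p_bmi=p_bmi,
                beta_gwg=b_gwg,
                p_gwg=p_gwg,
                n=len(cc),
            )
        )
    return out
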