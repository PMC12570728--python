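"""Shared data containers for the mediation pipeline.

The pipeline moves three objects between stages: a methylation beta-value
matrix (samples x CpG probes, values in [0, 1]), a per-sample phenotype
table (exposures, standardized birth weight, covariates, cord-blood
cell-type proportions), and — for simulated cohorts — the generative
ground truth used by parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "CohortTruth",
    "PHENOTYPE_COVARIATES",
    "validate_phenotypes",
]

#: Default adjustment covariates carried by every generated phenotype table.
PHENOTYPE_COVARIATES = ["maternal_age", "education", "country_of_birth", "smoking"]


@dataclass
class MethylationMatrix:
    """Samples x probes matrix of methylation beta values.

    Parameters
    ----------
    beta
        DataFrame indexed by sample id with one column per CpG probe.
        Entries are beta values in [0, 1]; NaN marks a missing call.
    """

    beta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            raise ValueError("duplicate sample ids in methylation matrix")
        if self.beta.columns.has_duplicates:
            raise ValueError("duplicate probe ids in methylation matrix")
        values = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0, 1] at sample "
                f"{self.beta.index[i]!r}, probe {self.beta.columns[j]!r}: "
                f"{values[i, j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]

    def subset_probes(self, probe_ids: list[str]) -> "MethylationMatrix":
        missing = [p for p in probe_ids if p not in self.beta.columns]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing}")
        return MethylationMatrix(self.beta.loc[:, probe_ids].copy())


@dataclass
class CohortTruth:
    """Generative ground truth of a simulated cohort.

    ``alpha_a`` holds the *realized* empirical exposure->mediator slopes on
    the beta scale (the generator plants slopes on the logit scale via a
    local linearization, so the realized beta-scale slope is what recovery
    tests should compare against).  ``expected_total_effect`` is
    ``direct_effect + sum(alpha_a * beta_m)``.
    """

    true_mediator_ids: list[str]
    alpha_a: np.ndarray
    beta_m: np.ndarray
    direct_effect: float
    expected_total_effect: float
    nominal_alpha_a: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.alpha_a = np.asarray(self.alpha_a, dtype=float)
        self.beta_m = np.asarray(self.beta_m, dtype=float)
        if len(self.true_mediator_ids) != self.alpha_a.size:
            raise ValueError("alpha_a length must match number of true mediators")
        if self.alpha_a.size != self.beta_m.size:
            raise ValueError("alpha_a and beta_m must have equal length")

    def to_dict(self) -> dict:
        return {
            "true_mediator_ids": list(self.true_mediator_ids),
            "alpha_a": self.alpha_a.tolist(),
            "beta_m": self.beta_m.tolist(),
            "direct_effect": float(self.direct_effect),
            "expected_total_effect": float(self.expected_total_effect),
            "nominal_alpha_a": (
                None
                if self.nominal_alpha_a is None
                else np.asarray(self.nominal_alpha_a, dtype=float).tolist()
            ),
        }


def validate_phenotypes(
    pheno: pd.DataFrame,
    cell_columns: list[str] | None = None,
    tol: float = 1e-8,
) -> None:
    """Check phenotype-table invariants.

    Cell-type proportion columns, where given, must lie on the probability
    simplex (non-negative, summing to one within ``tol``) for every sample
    with complete proportions.
    """
    if "sample_id" in pheno.columns and pheno["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype table")
    if cell_columns:
        missing = [c for c in cell_columns if c not in pheno.columns]
        if missing:
            raise KeyError(f"cell proportion columns absent: {missing}")
        props = pheno[cell_columns].to_numpy(dtype=float)
        complete = ~np.isnan(props).any(axis=1)
        if complete.any():
            sums = props[complete].sum(axis=1)
            if np.abs(sums - 1.0).max() > tol:
                raise ValueError("cell proportions do not sum to 1")
            if (props[complete] < -tol).any():
                raise ValueError("negative cell proportion")
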