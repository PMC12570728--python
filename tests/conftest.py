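import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import medipipe as mp
from medipipe.association import BMI_COVARIATES
from medipipe.pipeline import _numeric_covariates

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with three strongly planted mediators."""
    cfg = mp.SimulationConfig(
        n_samples=400,
        n_probes=600,
        alpha_a=[0.003] * 3,
        beta_m=[30.0] * 3,
        direct_effect=0.03,
        seed=11,
    )
    matrix, pheno, truth = mp.simulate_cohort(cfg)
    return cfg, matrix, pheno, truth


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted mediators and no direct effect."""
    cfg = mp.SimulationConfig(
        n_samples=300,
        n_probes=500,
        n_true_mediators=0,
        alpha_a=[],
        beta_m=[],
        direct_effect=0.0,
        seed=23,
    )
    matrix, pheno, truth = mp.simulate_cohort(cfg)
    return cfg, matrix, pheno, truth


def adjustment_matrix(pheno: pd.DataFrame, with_cells: bool = True) -> np.ndarray:
    cols = list(BMI_COVARIATES)
    if with_cells:
        # omit the last cell compartment (proportions sum to one)
        cells = [c for c in mp.simulate.CELL_TYPE_NAMES if c in pheno.columns]
        cols += cells[:-1]
    return _numeric_covariates(pheno, cols)
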