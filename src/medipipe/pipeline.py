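"""End-to-end pipeline: association screen -> high-dimensional mediator
selection -> classical mediation, with a reproducible result bundle.

``run_pipeline`` composes the three stages on in-memory inputs or files,
writes Table-shaped CSV/JSON outputs into a bundle directory, and logs
every seed, threshold and sample/probe attrition count to a run manifest.
Reruns with the same config and seed produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import (
    AdjustmentSpec,
    BMI_COVARIATES,
    DEFAULT_COVARIATES,
    encode_design,
    run_association_screen,
)
from .datatypes import MethylationMatrix
from .hidim import pool_candidates, run_all_methods
from .io import atomic_write_text, read_beta_matrix, read_phenotypes
from .mediation import (
    MediationModelSpec,
    bootstrap_mediation,
    select_serial_mediators,
)
from .simulate import CELL_TYPE_NAMES

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    beta_path: str | None = None
    pheno_path: str | None = None
    out_dir: str | None = None
    exposures: list[str] = field(default_factory=lambda: ["gwg", "bmi"])
    outcome: str = "z_birthweight"
    alpha: float = 0.05
    fdr_threshold: float = 0.05
    methods: list[str] = field(default_factory=lambda: ["hdma", "hima", "hima2"])
    screen_size: int | None = None
    cell_columns: list[str] = field(default_factory=lambda: list(CELL_TYPE_NAMES))
    n_boot: int = 1000
    estimators: list[str] = field(default_factory=lambda: ["robust", "ols"])
    max_serial: int = 3
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    status: str
    step1: pd.DataFrame
    flagged_exposures: list[str]
    step2: dict
    pooled: dict
    step3: dict
    manifest: dict


def _adjustment_spec(exposure: str) -> AdjustmentSpec:
    covs = BMI_COVARIATES if exposure == "bmi" else DEFAULT_COVARIATES
    covs = [c for c in covs if c != exposure]
    return AdjustmentSpec(exposure_name=exposure, covariate_names=covs)


def _numeric_covariates(pheno: pd.DataFrame, names: list[str]):
    design = encode_design(pheno, names, add_intercept=False)
    return design.to_numpy(dtype=float)


def run_pipeline(
    config: RunConfig,
    matrix: MethylationMatrix | None = None,
    pheno: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the three analysis steps and (optionally) write a bundle.

    Inputs come from ``config.beta_path`` / ``config.pheno_path`` unless
    given in memory.  If no exposure is significantly associated with the
    outcome in Step 1, the pipeline stops with status
    ``"no significant overall association"`` rather than raising.
    """
    if matrix is None:
        if config.beta_path is None:
            raise ValueError("no methylation matrix given")
        matrix = read_beta_matrix(config.beta_path)
    if pheno is None:
        if config.pheno_path is None:
            raise ValueError("no phenotype table given")
        pheno = read_phenotypes(config.pheno_path)

    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "n_samples": int(len(pheno)),
        "n_probes": int(matrix.n_probes),
        "stages": [],
    }

    # ----- Step 1: association screen ---------------------------------
    specs = [_adjustment_spec(e) for e in config.exposures]
    step1, flagged = run_association_screen(
        pheno, specs, alpha=config.alpha, outcome=config.outcome
    )
    manifest["stages"].append(
        {"stage": "association", "n_exposures": len(specs), "n_flagged": len(flagged)}
    )
    if not flagged:
        result = PipelineResult(
            status="no significant overall association",
            step1=step1,
            flagged_exposures=[],
            step2={},
            pooled={},
            step3={},
            manifest=manifest,
        )
        _write_bundle(config, result)
        return result

    # ----- Step 2: high-dimensional mediator selection ----------------
    cells = [c for c in config.cell_columns if c in pheno.columns]
    # proportions sum to one: omit the last compartment as the reference
    cells_adj = cells[:-1] if len(cells) > 1 else cells
    step2: dict = {}
    pooled: dict = {}
    aligned = pheno.set_index("sample_id").loc[matrix.sample_ids].reset_index()
    for exposure in flagged:
        spec = _adjustment_spec(exposure)
        cols = [exposure, config.outcome, *spec.covariate_names, *cells]
        ok = aligned[cols].notna().all(axis=1).to_numpy()
        sub = aligned[ok]
        beta_sub = matrix.beta.loc[ok]
        C = _numeric_covariates(sub, [*spec.covariate_names, *cells_adj])
        results = run_all_methods(
            beta_sub,
            sub[exposure].to_numpy(dtype=float),
            sub[config.outcome].to_numpy(dtype=float),
            covariates=C,
            d=config.screen_size,
            fdr_threshold=config.fdr_threshold,
            seed=config.seed,
            methods=tuple(config.methods),
        )
        probes, provenance = pool_candidates(
            list(results.values()), threshold=config.fdr_threshold
        )
        step2[exposure] = results
        pooled[exposure] = {"probes": probes, "provenance": provenance}
        manifest["stages"].append(
            {
                "stage": "hidim_mediation",
                "exposure": exposure,
                "n_samples_used": int(ok.sum()),
                "n_probes_in": int(matrix.n_probes),
                "n_probes_screened": len(next(iter(results.values())).screen.kept_probe_ids),
                "n_selected": {m: len(r.selected) for m, r in results.items()},
                "n_candidates": {m: len(r.candidates) for m, r in results.items()},
                "n_pooled": len(probes),
            }
        )

    # ----- Step 3: classical mediation on pooled candidates -----------
    step3: dict = {}
    for exposure in flagged:
        probes = pooled[exposure]["probes"]
        if not probes:
            step3[exposure] = {"status": "no pooled candidates"}
            continue
        spec1 = _adjustment_spec(exposure)
        sub = aligned
        C = _numeric_covariates(sub, spec1.covariate_names)
        x = sub[exposure].to_numpy(dtype=float)
        y = sub[config.outcome].to_numpy(dtype=float)
        M_cand = matrix.beta[probes]

        per_exposure: dict = {}
        for estimator in config.estimators:
            singles = []
            for probe in probes:
                mspec = MediationModelSpec(
                    exposure_name=exposure.upper(),
                    mediator_ids=[probe],
                    topology="single",
                    estimator=estimator,
                    n_boot=config.n_boot,
                    covariate_names=spec1.covariate_names,
                    outcome_name=config.outcome,
                    seed=config.seed,
                )
                singles.append(bootstrap_mediation(M_cand, x, y, C, mspec))
            serial_ids = select_serial_mediators(singles, min(config.max_serial, len(probes)))
            models = {"single": singles}
            if len(serial_ids) >= 2:
                sspec = MediationModelSpec(
                    exposure_name=exposure.upper(),
                    mediator_ids=serial_ids,
                    topology="serial",
                    estimator=estimator,
                    n_boot=config.n_boot,
                    covariate_names=spec1.covariate_names,
                    outcome_name=config.outcome,
                    seed=config.seed,
                )
                models["serial"] = bootstrap_mediation(M_cand, x, y, C, sspec)
            if len(probes) >= 2:
                pspec = MediationModelSpec(
                    exposure_name=exposure.upper(),
                    mediator_ids=list(probes),
                    topology="parallel",
                    estimator=estimator,
                    n_boot=config.n_boot,
                    covariate_names=spec1.covariate_names,
                    outcome_name=config.outcome,
                    seed=config.seed,
                )
                models["parallel"] = bootstrap_mediation(M_cand, x, y, C, pspec)
            per_exposure[estimator] = models
        step3[exposure] = per_exposure
        manifest["stages"].append(
            {
                "stage": "classical_mediation",
                "exposure": exposure,
                "n_candidates": len(probes),
                "estimators": list(config.estimators),
                "n_boot": config.n_boot,
            }
        )

    result = PipelineResult(
        status="complete",
        step1=step1,
        flagged_exposures=flagged,
        step2=step2,
        pooled=pooled,
        step3=step3,
        manifest=manifest,
    )
    _write_bundle(config, result)
    return result


def _decomposition_json(dec) -> dict:
    return {
        "pathways": [
            {
                "label": pw.label,
                "chain": list(pw.mediator_chain),
                "estimate": pw.estimate,
                "ci_low": pw.ci_low,
                "ci_high": pw.ci_high,
                "significant": pw.significant,
            }
            for pw in dec.pathways
        ],
        "total_indirect": dec.total_indirect,
        "total_indirect_ci": dec.total_indirect_ci,
        "direct": {"estimate": dec.direct[0], "se": dec.direct[1], "p": dec.direct[2]},
        "total": {"estimate": dec.total[0], "se": dec.total[1], "p": dec.total[2]},
        "n_used": dec.n_used,
    }


def _write_bundle(config: RunConfig, result: PipelineResult) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    header = f"# config_hash={config.config_hash()} seed={config.seed}\n"
    atomic_write_text(out / "step1_associations.csv", header + result.step1.to_csv(index=False))

    for exposure, methods in result.step2.items():
        for name, res in methods.items():
            atomic_write_text(
                out / f"step2_{exposure}_{name}.csv",
                header + res.to_frame().to_csv(index=False),
            )
        prov = result.pooled[exposure]["provenance"]
        pooled_frame = pd.DataFrame(
            [
                {
                    "probe_id": probe,
                    **{
                        m.upper(): m.upper() in [x.upper() for x in prov[probe]]
                        for m in config.methods
                    },
                }
                for probe in result.pooled[exposure]["probes"]
            ]
        )
        atomic_write_text(
            out / f"step2_{exposure}_pooled.csv", header + pooled_frame.to_csv(index=False)
        )

    step3_json = {}
    for exposure, per_est in result.step3.items():
        if "status" in per_est:
            step3_json[exposure] = per_est
            continue
        step3_json[exposure] = {}
        for estimator, models in per_est.items():
            block = {}
            for name, dec in models.items():
                if name == "single":
                    block["single"] = [_decomposition_json(d) for d in dec]
                else:
                    block[name] = _decomposition_json(dec)
                    atomic_write_text(
                        out / f"step3_{exposure}_{estimator}_{name}.csv",
                        header + dec.to_frame().to_csv(index=False),
                    )
            step3_json[exposure][estimator] = block
    atomic_write_text(
        out / "step3_decompositions.json",
        json.dumps(step3_json, indent=2, sort_keys=True, default=float),
    )
    atomic_write_text(out / "run_config.yaml", config.to_yaml())
    atomic_write_text(
        out / "run_manifest.json",
        json.dumps(result.manifest, indent=2, sort_keys=True),
    )
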