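"""End-to-end orchestration: synthetic cohort -> slope classification ->
trajectory modelling of the improved subcohort -> phenotypes -> mortality
models -> structured report.

Each stage is the corresponding module's public API; this file only wires
them together, logs stage sizes, and persists intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations, cohort as cohort_mod, phenotype, trajectory
from .bayes_slope import SlopeModelSpec, fit_hierarchical_model
from .cohort import CohortConfig
from .egfr_core import DAYS_PER_YEAR, annualize_egfr
from .phenotype import PhenotypeRule
from .synthetic import GeneratorConfig, generate_cohort
from .trajectory import TrajectoryModelSpec

log = logging.getLogger("egfr_traj")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "death_year_indicator"]


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    slope: SlopeModelSpec = field(default_factory=SlopeModelSpec)
    # trajectory selection at pipeline scale: candidate counts 1..6 and a
    # handful of EM restarts keep the full run inside a desk-scale budget
    trajectory: TrajectoryModelSpec = field(
        default_factory=lambda: TrajectoryModelSpec(
            k_range=tuple(range(1, 7)), n_restarts=5
        )
    )
    phenotype_rule: PhenotypeRule = field(default_factory=PhenotypeRule)
    horizons: tuple = (1.0, 3.0, 5.0, 9.0)
    seed: int = 0

    def reseeded(self, seed: int) -> "PipelineConfig":
        """Copy of the config with every stage seed derived from ``seed``."""
        rng = np.random.default_rng(seed)
        sub = rng.integers(0, 2**31 - 1, size=3)
        return dataclasses.replace(
            self,
            generator=dataclasses.replace(self.generator, seed=int(sub[0])),
            slope=dataclasses.replace(self.slope, seed=int(sub[1])),
            trajectory=dataclasses.replace(self.trajectory, seed=int(sub[2])),
            seed=seed,
        )


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    exclusions: pd.DataFrame
    slope_table: pd.DataFrame
    slope_fit: object
    annual: pd.DataFrame | None
    trajectory_fit: object | None
    group_summaries: pd.DataFrame | None
    phenotype_labels: pd.DataFrame | None
    phenotype_patients: pd.DataFrame | None
    cox_fits: dict
    phenotype_cox_fits: dict | None
    multinomial_fit: object
    report: dict


def death_year_indicator(
    annual: pd.DataFrame, cohort: pd.DataFrame, patients: pd.DataFrame
) -> pd.Series:
    """Pattern-mixture indicator d_i: the patient died during follow-up and
    has an eGFR measurement in the post-T0 year of their death."""
    merged = cohort.merge(
        patients[["patient_id", "death_date"]], on="patient_id", how="left"
    )
    death_year = (
        (pd.to_datetime(merged["death_date"]) - pd.to_datetime(merged["t0_date"]))
        .dt.days
        / DAYS_PER_YEAR
    )
    death_year = np.floor(death_year)
    merged["death_year_index"] = death_year
    have = annual.merge(
        merged[["patient_id", "death_year_index"]], on="patient_id"
    )
    hit = have[have["year_index"] == have["death_year_index"]]
    d = pd.Series(0, index=cohort["patient_id"], dtype=int)
    d.loc[d.index.isin(hit["patient_id"])] = 1
    return d


def run_pipeline(config: PipelineConfig = PipelineConfig(), out_dir=None):
    """Run every stage on a synthetic cohort and return a PipelineResult."""
    log.info("generating synthetic cohort: n=%d", config.generator.n_patients)
    synth = generate_cohort(config.generator)
    log.info("measurement rows: %d", len(synth.measurements))

    cohort, exclusions = cohort_mod.build_cohort(
        synth.measurements, synth.patients, config.cohort
    )
    log.info("cohort built: n=%d (excluded %d)", len(cohort), len(exclusions))

    points = cohort_mod.pre_t0_points(
        synth.measurements, synth.patients, cohort, config.cohort
    )
    slope_fit = fit_hierarchical_model(points, config.slope)
    slope_table = slope_fit.to_frame()
    log.info(
        "slope classes: %s",
        slope_table["slope_class"].value_counts().to_dict(),
    )
    merged = cohort.merge(slope_table, on="patient_id", how="left")

    cox_fits = {}
    for h in config.horizons:
        spec = associations.ModelSpec(outcome_horizon=h)
        cox_fits[h] = associations.fit_cox(merged, spec)
        log.info("cox horizon %.0fy: n=%d events=%d", h, cox_fits[h].n, cox_fits[h].events)
    multinomial_fit = associations.fit_multinomial(
        merged,
        associations.ModelSpec(
            covariates=tuple(
                c if c != "t0_egfr" else "initial_egfr"
                for c in associations.DEFAULT_COVARIATES
            )
        ),
    )

    improved = merged[merged["slope_class"] == "improved"]
    annual = traj_fit = summaries = labels = pheno_patients = None
    pheno_cox = None
    if len(improved) >= max(config.trajectory.k_range) * 3:
        post = cohort_mod.post_t0_points(
            synth.measurements, synth.patients, improved, config.cohort
        )
        t0_map = improved.set_index("patient_id")["t0_date"]
        annual = annualize_egfr(post, t0_map)
        d = death_year_indicator(annual, improved, synth.patients)
        traj_fit = trajectory.select_num_groups(annual, d, config.trajectory)
        log.info("selected K=%d trajectory groups", traj_fit.K)
        summaries = trajectory.summarize_groups(traj_fit, annual)
        labels, pheno_patients = phenotype.map_all_groups(
            summaries, traj_fit.memberships, config.phenotype_rule
        )
        # phenotype mortality models: improved patients labelled by their
        # phenotype, compared with the stable-slope reference group
        pheno_cohort = merged[merged["slope_class"].isin(["improved", "stable"])]
        pheno_map = pheno_patients.set_index("patient_id")["phenotype"]
        pheno_cohort = pheno_cohort.copy()
        pheno_cohort["phenotype"] = np.where(
            pheno_cohort["slope_class"] == "stable",
            "stable",
            pheno_cohort["patient_id"].map(pheno_map),
        )
        pheno_cohort = pheno_cohort.dropna(subset=["phenotype"])
        pheno_cox = {}
        for h in config.horizons:
            spec = associations.ModelSpec(
                outcome_horizon=h, exposure="phenotype", reference="stable"
            )
            pheno_cox[h] = associations.fit_cox(pheno_cohort, spec)
    else:
        log.info("improved subcohort too small; trajectory stage skipped")

    report = associations.build_report(
        cohort,
        slope_table,
        cox_fits,
        multinomial_fit,
        traj_fit.selection_ladder if traj_fit is not None else None,
        summaries,
        labels,
        pheno_cox,
    )
    result = PipelineResult(
        cohort=cohort,
        exclusions=exclusions,
        slope_table=slope_table,
        slope_fit=slope_fit,
        annual=annual,
        trajectory_fit=traj_fit,
        group_summaries=summaries,
        phenotype_labels=labels,
        phenotype_patients=pheno_patients,
        cox_fits=cox_fits,
        phenotype_cox_fits=pheno_cox,
        multinomial_fit=multinomial_fit,
        report=report,
    )
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.cohort.to_csv(out_dir / "cohort.csv", index=False)
    result.exclusions.to_csv(out_dir / "exclusions.csv", index=False)
    result.slope_table.to_csv(out_dir / "slopes.csv", index=False)
    if result.annual is not None:
        result.annual.to_csv(out_dir / "annual_egfr.csv", index=False)
    if result.trajectory_fit is not None:
        fit = result.trajectory_fit
        with open(out_dir / "trajectories.json", "w") as fh:
            json.dump(
                {
                    "K": fit.K,
                    "beta": fit.beta.tolist(),
                    "gamma": fit.gamma,
                    "delta": fit.delta.tolist(),
                    "pi": fit.pi.tolist(),
                    "sigma2": fit.sigma2,
                    "bic": fit.bic,
                    "appa": fit.appa.tolist(),
                    "ladder": fit.selection_ladder.to_dict(orient="records"),
                },
                fh,
                indent=2,
            )
        fit.memberships.to_csv(out_dir / "memberships.csv", index=False)
    if result.phenotype_labels is not None:
        result.phenotype_labels.to_csv(out_dir / "phenotypes.csv", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
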