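"""End-to-end orchestration: census framework -> disease -> medications ->
imputation -> adjustment, with seeded replicates and a run manifest.

The in-memory entry point is :func:`synthesize_population`; the file-based
:func:`build_population` wraps it with I/O, stage logging and a manifest
(seeds, row counts, per-stage checksums) sufficient to reproduce a run
exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .adjust import apply_mean_shift, compute_adjustment
from .categories import disease_state, medication_state
from .cpt import (
    assign_disease_state,
    assign_medication_state,
    estimate_cpt,
)
from .errors import ValidationError
from .framework import (
    SuppressionResolutionPolicy,
    expand_strata,
    redistribute_unknowns,
    resolve_suppressed_cells,
)
from .impute import ImputationConfig, extract_synthetic, run_chained_imputation, \
    stack_for_imputation
from .validate import replicate_variability

logger = logging.getLogger(__name__)

DISEASE_CONDITIONING = ["age_band", "sex", "ethnicity"]
MEDICATION_CONDITIONING = ["age_band", "sex", "ethnicity", "prior_cvd"]


@dataclass
class PipelineConfig:
    """One run's inputs, stage settings and seed (no wall-clock seeding)."""

    census_path: str
    admin_path: str
    cohort_path: str
    out_dir: str
    master_seed: int
    smoking_mode: str = "monte_carlo"
    suppression_strategy: str = "uniform_1_5"
    min_cell: int = 20
    medication_condition_on_diabetes: bool = False
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    adjustment_references: dict[str, str] = field(default_factory=dict)
    do_adjustment: bool = True
    n_replicates: int = 1

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "master_seed" not in raw:
            raise ValidationError("config must set master_seed explicitly")
        imp = ImputationConfig(**raw.pop("imputation", {}))
        return cls(imputation=imp, **raw)


def _stage_rngs(seed: int, framework_seed: int | None = None
                ) -> dict[str, np.random.Generator]:
    """Independent per-stage RNG streams spawned from the run seed.

    ``framework_seed`` (when given) seeds the suppression-resolution stage
    separately, so replicate populations built from different run seeds
    share one resolved census — keeping their demographic margins
    identical, as replicates of the same frame should be.
    """
    names = ["suppression", "expansion", "disease", "medications", "imputation"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    rngs = {n: np.random.default_rng(s) for n, s in zip(names, children)}
    if framework_seed is not None:
        rngs["suppression"] = np.random.default_rng(
            np.random.SeedSequence(framework_seed).spawn(1)[0])
    return rngs


def estimate_admin_cpts(
    admin: pd.DataFrame,
    min_cell: int = 20,
    condition_on_diabetes: bool = False,
):
    """Disease and medication CPTs from linked administrative records.

    The disease CPT conditions on age band, sex and ethnicity; the
    medication CPT additionally conditions on prior CVD (and optionally on
    diabetes, mirroring the linkage variables of the dispensing source).
    """
    admin = admin.copy()
    admin["disease_state"] = disease_state(admin["diabetes"], admin["prior_cvd"])
    admin["medication_state"] = medication_state(admin["ll_med"], admin["bpl_med"])
    cpt_disease = estimate_cpt(
        admin, DISEASE_CONDITIONING, "disease_state", min_cell=min_cell)
    med_cond = MEDICATION_CONDITIONING + (
        ["diabetes"] if condition_on_diabetes else [])
    cpt_meds = estimate_cpt(admin, med_cond, "medication_state", min_cell=min_cell)
    return cpt_disease, cpt_meds


def synthesize_population(
    census: pd.DataFrame,
    admin: pd.DataFrame,
    cohort: pd.DataFrame,
    seed: int,
    smoking_mode: str = "monte_carlo",
    suppression_strategy: str = "uniform_1_5",
    min_cell: int = 20,
    medication_condition_on_diabetes: bool = False,
    imputation: ImputationConfig | None = None,
    adjustment_references: dict[str, pd.DataFrame] | None = None,
    id_prefix: str = "p",
    framework_seed: int | None = None,
) -> dict:
    """Run every stage in memory; returns the populations and stage records.

    The result dict carries ``population`` (final), ``unadjusted`` (before
    any post-hoc mean shift) and a ``stages`` log of row counts.
    """
    rngs = _stage_rngs(seed, framework_seed)
    stages: list[dict] = []

    strata = resolve_suppressed_cells(
        census, SuppressionResolutionPolicy(strategy=suppression_strategy),
        rng=rngs["suppression"])
    strata = redistribute_unknowns(strata)
    stages.append({"stage": "framework", "strata": len(strata)})

    pop = expand_strata(strata, rngs["expansion"], smoking_mode=smoking_mode,
                        id_prefix=id_prefix)
    stages.append({"stage": "expansion", "persons": len(pop)})

    cpt_disease, cpt_meds = estimate_admin_cpts(
        admin, min_cell=min_cell,
        condition_on_diabetes=medication_condition_on_diabetes)
    pop = assign_disease_state(pop, cpt_disease, rngs["disease"])
    pop = assign_medication_state(pop, cpt_meds, rngs["medications"])
    stages.append({"stage": "disease_medications", "persons": len(pop)})

    imputation = imputation or ImputationConfig()
    stacked = stack_for_imputation(cohort, pop)
    completed = run_chained_imputation(stacked, imputation, rngs["imputation"])
    pop = extract_synthetic(completed)
    stages.append({"stage": "imputation", "persons": len(pop)})

    unadjusted = pop.copy()
    if adjustment_references:
        for variable, reference in adjustment_references.items():
            spec = compute_adjustment(pop, reference, variable)
            pop = apply_mean_shift(pop, spec)
            stages.append({"stage": f"adjustment:{variable}",
                           "strata": len(spec.delta)})

    return {"population": pop, "unadjusted": unadjusted, "stages": stages,
            "cpt_disease": cpt_disease, "cpt_meds": cpt_meds}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_population(cfg: PipelineConfig, seed: int | None = None,
                     tag: str = "", framework_seed: int | None = None) -> dict:
    """File-based pipeline run: read inputs, synthesize, write outputs.

    Emits ``population{tag}.csv`` (adjusted when references are configured)
    and ``population{tag}_unadjusted.csv``, plus ``manifest{tag}.json``
    recording the seed, stage row counts and output checksums.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg.master_seed if seed is None else seed

    census = tio.read_census_crosstab(cfg.census_path)
    admin = tio.read_admin_records(cfg.admin_path)
    cohort = tio.read_cohort(cfg.cohort_path)
    references = None
    if cfg.do_adjustment and cfg.adjustment_references:
        references = {
            var: tio.read_reference_table(path)
            for var, path in cfg.adjustment_references.items()
        }

    result = synthesize_population(
        census, admin, cohort, seed,
        smoking_mode=cfg.smoking_mode,
        suppression_strategy=cfg.suppression_strategy,
        min_cell=cfg.min_cell,
        medication_condition_on_diabetes=cfg.medication_condition_on_diabetes,
        imputation=cfg.imputation,
        adjustment_references=references,
        framework_seed=framework_seed,
    )

    pop_path = out_dir / f"population{tag}.csv"
    raw_path = out_dir / f"population{tag}_unadjusted.csv"
    tio.write_population(result["population"], pop_path)
    tio.write_population(result["unadjusted"], raw_path)
    manifest = {
        "seed": int(seed),
        "inputs": {
            "census": cfg.census_path,
            "admin": cfg.admin_path,
            "cohort": cfg.cohort_path,
        },
        "stages": result["stages"],
        "rows": len(result["population"]),
        "outputs": {
            str(pop_path): _sha256(pop_path),
            str(raw_path): _sha256(raw_path),
        },
    }
    with open(out_dir / f"manifest{tag}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("wrote %s (%d persons)", pop_path, len(result["population"]))
    return manifest


def build_replicates(cfg: PipelineConfig, n_replicates: int | None = None
                     ) -> list[dict]:
    """Build n replicate populations with seeds spawned from the master seed.

    Replicates share their demographic margins (deterministic stage) and
    differ in every stochastic field; the per-replicate manifests are
    returned in order.
    """
    n = n_replicates or cfg.n_replicates
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(cfg.master_seed).spawn(n)]
    manifests = []
    for r, seed in enumerate(seeds):
        manifests.append(build_population(cfg, seed=seed, tag=f"_r{r}",
                                          framework_seed=cfg.master_seed))
    return manifests


def replicate_report(cfg: PipelineConfig, n_replicates: int,
                     summaries: list[dict]) -> pd.DataFrame:
    """Across-replicate variability of stratum summaries (in memory)."""
    census = tio.read_census_crosstab(cfg.census_path)
    admin = tio.read_admin_records(cfg.admin_path)
    cohort = tio.read_cohort(cfg.cohort_path)

    def build(seed: int) -> pd.DataFrame:
        return synthesize_population(
            census, admin, cohort, seed,
            smoking_mode=cfg.smoking_mode,
            min_cell=cfg.min_cell,
            imputation=cfg.imputation,
        )["population"]

    return replicate_variability(build, cfg.master_seed, n_replicates, summaries)
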