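"""Run configuration, cohort IO and the two headline analyses.

`run_univariate` executes: cohort (synthetic or from files) -> mean
imputation -> full-cohort deconfounding -> composite target -> age-quartile
moderation permutation test -> BH FDR -> enrichment summaries -> coefficient
similarity tables.  `run_multivariate` executes: median age split -> shared
fold plan -> six elastic net train/test regimes with within-fold
preprocessing -> per-repetition outcomes -> planned regime contrasts ->
coefficient-by-category summary.  Both write delimited text tables plus a
JSON manifest recording seeds, sizes and library versions, so a run is fully
reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cogtarget import build_composite, screen_and_rank_traits
from .crossage import (
    ElasticNetSpec,
    compare_regimes,
    make_fold_plan,
    run_generalization,
    split_median,
    summarize_coefficients_by_category,
)
from .deconfound import apply_deconfound, build_confound_design, fit_deconfound, impute_mean
from .synthdata import Cohort, CohortConfig, GenerativeTruth, generate_cohort
from .unimod import (
    QuartileModel,
    assign_age_quartiles,
    coefficient_similarity,
    enrichment_by_quartile,
    permutation_moderation_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "write_cohort",
    "read_cohort",
    "run_univariate",
    "run_multivariate",
    "deconfounded_inputs",
    "moderation_analysis",
]


@dataclass
class RunConfig:
    """Settings for the two analyses; defaults mirror the full-scale study."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_dir: str | None = None  # read cohort from files instead of simulating
    variance_threshold: float = 0.85
    age_deconfound: bool = True
    control_no_age: bool = False  # also run the no-age-deconfounding control
    composite_k: int = 30
    screen_traits: bool = False  # rank traits by brain predictability first
    coverage_threshold: float = 0.8
    n_perm: int = 10000
    storey_lambda: float = 0.5
    k_folds: int = 10
    repeats: int = 10
    enet: ElasticNetSpec = field(default_factory=ElasticNetSpec)
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        cohort = raw.pop("cohort", None)
        enet = raw.pop("enet", None)
        cfg = cls(**raw)
        if cohort:
            cfg.cohort = CohortConfig.from_dict({**cfg.cohort.to_dict(), **cohort})
        if enet:
            cfg.enet = dataclasses.replace(cfg.enet, **enet)
        return cfg


# ---------------------------------------------------------------------------
# cohort IO: three delimited tables + a JSON sidecar
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort as subjects+confounds, IDPs and traits CSVs plus a sidecar.

    Missing entries serialize as empty fields and restore as NaN/masked.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = pd.concat(
        [cohort.subjects.reset_index(drop=True),
         cohort.essential.reset_index(drop=True),
         cohort.nuisance.reset_index(drop=True)],
        axis=1,
    )
    subjects.to_csv(out / "subjects.csv", index=False)
    idps = cohort.idps.copy()
    idps.insert(0, "subject_id", cohort.subjects["subject_id"].to_numpy())
    idps.to_csv(out / "idps.csv", index=False)
    traits = cohort.traits.copy()
    traits.insert(0, "subject_id", cohort.subjects["subject_id"].to_numpy())
    traits.to_csv(out / "traits.csv", index=False)
    sidecar = {
        "essential_columns": list(cohort.essential.columns),
        "nuisance_columns": list(cohort.nuisance.columns),
        "idp_categories": cohort.idp_categories.to_dict(),
        "config": cohort.config.to_dict() if cohort.config else None,
        "truth": cohort.truth.to_dict() if cohort.truth else None,
    }
    (out / "cohort.json").write_text(json.dumps(sidecar))


def read_cohort(indir: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`; round-trips exactly."""
    ind = Path(indir)
    for name in ("subjects.csv", "idps.csv", "traits.csv", "cohort.json"):
        if not (ind / name).exists():
            raise FileNotFoundError(f"missing cohort file: {ind / name}")
    sidecar = json.loads((ind / "cohort.json").read_text())
    subjects_full = pd.read_csv(ind / "subjects.csv")
    idps = pd.read_csv(ind / "idps.csv").drop(columns=["subject_id"])
    traits = pd.read_csv(ind / "traits.csv").drop(columns=["subject_id"])
    ess_cols = sidecar["essential_columns"]
    nuis_cols = sidecar["nuisance_columns"]
    missing = [c for c in ["subject_id", "age", "sex", *ess_cols, *nuis_cols]
               if c not in subjects_full.columns]
    if missing:
        raise ValueError(f"subjects table missing columns: {missing}")
    config = CohortConfig.from_dict(sidecar["config"]) if sidecar.get("config") else None
    truth = GenerativeTruth.from_dict(sidecar["truth"]) if sidecar.get("truth") else None
    cats = pd.Series(sidecar["idp_categories"], name="category")
    cohort = Cohort(
        subjects=subjects_full[["subject_id", "age", "sex"]].copy(),
        essential=subjects_full[ess_cols].copy(),
        nuisance=subjects_full[nuis_cols].copy(),
        idps=idps,
        idp_categories=cats.reindex(idps.columns),
        traits=traits,
        idp_mask=idps.isna().to_numpy(),
        trait_mask=traits.isna().to_numpy(),
        config=config,
        truth=truth,
    )
    cohort.validate()
    return cohort


def _load_cohort(config: RunConfig) -> Cohort:
    if config.cohort_dir:
        return read_cohort(config.cohort_dir)
    return generate_cohort(config.cohort)


def _manifest(config: RunConfig, cohort: Cohort, extra: dict) -> dict:
    return {
        "agemod_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "cohort_seed": cohort.config.seed if cohort.config else None,
        "n_subjects": cohort.n_subjects,
        "n_idps": cohort.idps.shape[1],
        "n_traits": cohort.traits.shape[1],
        **extra,
    }


def deconfounded_inputs(
    cohort: Cohort, variance_threshold: float = 0.85, age_terms: bool = True
):
    """Full-cohort impute + deconfound of IDPs and traits (univariate mode).

    Returns (IDP residuals, deconfounded trait frame, confound design,
    complete-trait row mask); trait-incomplete subjects are excluded, as in
    the cohort definition.
    """
    X, idp_means = impute_mean(cohort.idps)
    design = build_confound_design(
        cohort.essential, cohort.nuisance, variance_threshold, age_terms=age_terms
    )
    dm_idp = fit_deconfound(design, cohort.essential, cohort.nuisance, X)
    X_res = apply_deconfound(dm_idp, cohort.essential, cohort.nuisance, X)
    complete = ~cohort.trait_mask.any(axis=1)
    if not complete.all():
        logger.info("excluding %d subjects with missing trait values", (~complete).sum())
    traits = cohort.traits.loc[complete].reset_index(drop=True)
    dm_tr = fit_deconfound(
        design, cohort.essential.loc[complete], cohort.nuisance.loc[complete], traits
    )
    T_res = pd.DataFrame(
        apply_deconfound(dm_tr, cohort.essential.loc[complete],
                         cohort.nuisance.loc[complete], traits),
        columns=traits.columns,
    )
    return X_res[complete], T_res, design, complete


def moderation_analysis(
    cohort: Cohort,
    n_perm: int = 10000,
    seed: int = 0,
    variance_threshold: float = 0.85,
    age_terms: bool = True,
    composite_k: int | None = None,
    keep_archive: bool = True,
):
    """Deconfound, build the composite target, and run the moderation test.

    The shared univariate path: full-cohort deconfounding, first-PC composite
    over the (deconfounded) traits, age-quartile assignment, and the
    label-permutation moderation test.  Returns (ModerationTestResult,
    QuartileAssignment, ConfoundDesign).
    """
    X_res, T_res, design, complete = deconfounded_inputs(
        cohort, variance_threshold, age_terms
    )
    K = min(composite_k or T_res.shape[1], T_res.shape[1])
    _, cog = build_composite(T_res, K=K)
    quart = assign_age_quartiles(cohort.ages[complete])
    result = permutation_moderation_test(
        X_res, cog, quart, n_perm=n_perm, seed=seed, keep_archive=keep_archive
    )
    result.idp_names = list(cohort.idps.columns)
    return result, quart, design


def run_univariate(config: RunConfig) -> dict:
    """Quartile-stratified univariate moderation analysis; writes a report bundle."""
    cohort = _load_cohort(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    X_res, T_res, design, complete = deconfounded_inputs(
        cohort, config.variance_threshold, config.age_deconfound
    )
    ranked = None
    if config.screen_traits:
        ranked = screen_and_rank_traits(
            X_res, T_res, coverage_threshold=config.coverage_threshold, seed=config.seed
        )
    K = min(config.composite_k, T_res.shape[1])
    _, cog = build_composite(T_res, K=K, ranked=ranked)

    ages = cohort.ages[complete]
    quart = assign_age_quartiles(ages)
    result = permutation_moderation_test(
        X_res, cog, quart, n_perm=config.n_perm, seed=config.seed
    )
    result.idp_names = list(cohort.idps.columns)
    enrich = enrichment_by_quartile(result, lam=config.storey_lambda)
    similarity = coefficient_similarity(result.slopes)

    coef = QuartileModel(
        intercepts=result.intercepts, slopes=result.slopes, contrasts=result.contrasts,
        idp_names=list(cohort.idps.columns),
    ).to_frame()
    coef.to_csv(out / "quartile_coefficients.csv")
    result.p_frame().to_csv(out / "moderation_pvalues.csv")
    (out / "enrichment.json").write_text(
        json.dumps({q: s.to_dict() for q, s in enrich.items()}, indent=2)
    )
    for name, table in similarity.items():
        table.to_csv(out / f"similarity_{name}.csv")

    bundle = {"cohort": cohort, "result": result, "enrichment": enrich,
              "similarity": similarity, "design": design, "quartiles": quart}

    if config.control_no_age:
        Xc, Tc, _, comp_c = deconfounded_inputs(
            cohort, config.variance_threshold, age_terms=False
        )
        _, cog_c = build_composite(Tc, K=K)
        quart_c = assign_age_quartiles(cohort.ages[comp_c])
        ctrl = permutation_moderation_test(
            Xc, cog_c, quart_c, n_perm=max(1, min(config.n_perm, 100)),
            seed=config.seed, keep_archive=False,
        )
        QuartileModel(intercepts=ctrl.intercepts, slopes=ctrl.slopes, contrasts=ctrl.contrasts,
           idp_names=list(cohort.idps.columns)).to_frame().to_csv(
            out / "quartile_coefficients_no_age_deconfound.csv"
        )
        bundle["control_no_age"] = ctrl

    manifest = _manifest(config, cohort, {
        "analysis": "univariate", "n_perm": config.n_perm,
        "n_retained_confound_pcs": design.n_retained,
        "n_pvalues": int(result.p_values.size),
        "storey_lambda": config.storey_lambda,
        "age_deconfound": config.age_deconfound,
    })
    (out / "manifest_univariate.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle


def run_multivariate(config: RunConfig) -> dict:
    """Six-regime cross-age elastic net generalization; writes a report bundle."""
    cohort = _load_cohort(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    complete = ~cohort.trait_mask.any(axis=1)
    if not complete.all():
        logger.info("excluding %d subjects with missing trait values", (~complete).sum())
        cohort = Cohort(
            subjects=cohort.subjects.loc[complete].reset_index(drop=True),
            essential=cohort.essential.loc[complete].reset_index(drop=True),
            nuisance=cohort.nuisance.loc[complete].reset_index(drop=True),
            idps=cohort.idps.loc[complete].reset_index(drop=True),
            idp_categories=cohort.idp_categories,
            traits=cohort.traits.loc[complete].reset_index(drop=True),
            idp_mask=cohort.idp_mask[complete.to_numpy() if hasattr(complete, "to_numpy") else complete],
            trait_mask=cohort.trait_mask[complete.to_numpy() if hasattr(complete, "to_numpy") else complete],
            config=cohort.config,
            truth=cohort.truth,
        )

    groups = split_median(cohort.ages)
    plan = make_fold_plan(groups, k=config.k_folds, repeats=config.repeats, seed=config.seed)
    K = min(config.composite_k, cohort.traits.shape[1])
    res = run_generalization(
        cohort, plan, enet=config.enet, variance_threshold=config.variance_threshold,
        K=K, seed=config.seed,
    )
    contrasts = compare_regimes(res["outcomes"])

    res["outcomes"].to_csv(out / "regime_outcomes.csv", index=False)
    res["fold_log"].drop(columns=[], errors="ignore").to_csv(out / "fold_log.csv", index=False)
    contrasts.to_csv(out / "regime_contrasts.csv", index=False)
    with open(out / "hyperparameters.jsonl", "w") as fh:
        for _, row in res["fold_log"].iterrows():
            fh.write(json.dumps({
                "repeat": int(row["repeat"]), "fold": int(row["fold"]),
                "regime": row["regime"], "alpha": row["alpha"], "rho": row["rho"],
            }) + "\n")

    cats = cohort.idp_categories.to_numpy()
    by_cat = {}
    for train_g in ("young", "old", "pooled"):
        coefs = np.array([c["coef"] for c in res["coefs"] if c["train"] == train_g])
        by_cat[train_g] = summarize_coefficients_by_category(coefs, cats)
    cat_table = pd.DataFrame(by_cat)
    cat_table.to_csv(out / "coef_by_category.csv")

    manifest = _manifest(config, cohort, {
        "analysis": "multivariate", "k_folds": config.k_folds, "repeats": config.repeats,
        "n_outcome_rows": int(len(res["outcomes"])),
        "n_out_of_sample_estimates_per_group": int(config.k_folds * config.repeats),
    })
    (out / "manifest_multivariate.json").write_text(json.dumps(manifest, indent=2))
    return {**res, "contrasts": contrasts, "coef_by_category": cat_table,
            "plan": plan, "cohort": cohort, "manifest": manifest}
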