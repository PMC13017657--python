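"""Cross-age elastic net generalization framework.

The cohort is split at the median age into young and old halves and an
elastic net predicting the composite cognitive target from all IDPs is
evaluated under six train/test regimes: within-group (young->young,
old->old), across-group (young->old, old->young) and pooled training
(size-matched subsample of both halves, tested on each half).  Evaluation
uses k-fold cross-validation repeated several times; test folds of a given
repetition are shared across regimes, so per-repetition accuracies are
paired and regimes can be compared with exact Wilcoxon signed-rank tests.

All preprocessing (mean imputation, confound design + deconfounding of IDPs
and traits, composite construction, feature standardisation) is fitted on
each regime's training rows only and applied frozen to the test fold, and
hyperparameters (alpha, rho) are selected by nested inner cross-validation
on the scikit-learn elastic net objective

    (1/2n) ||y - X b||^2 + alpha * (rho ||b||_1 + (1-rho)/2 ||b||^2).

Accuracy is the Pearson r between predictions and observed targets,
Fisher-z-averaged over folds, plus RMSE and %dRMSE against a mean-predictor
null whose RMSE is the test target's (population) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from ._rng import substream
from .cogtarget import apply_composite, build_composite
from .deconfound import apply_deconfound, build_confound_design, fit_deconfound, impute_mean
from .unimod import bh_adjust

__all__ = [
    "REGIMES",
    "ElasticNetSpec",
    "FoldPlan",
    "split_median",
    "make_fold_plan",
    "subsample_pooled",
    "fit_elastic_net",
    "train_elastic_net_nested",
    "evaluate_predictions",
    "fisher_z_mean",
    "run_generalization",
    "compare_regimes",
    "summarize_coefficients_by_category",
    "relative_reduction",
    "PLANNED_CONTRASTS",
]

YOUNG, OLD, POOLED = "young", "old", "pooled"

#: The six train/test regimes: within-group, across-group and pooled training.
REGIMES: list[tuple[str, str]] = [
    (YOUNG, YOUNG),
    (OLD, OLD),
    (YOUNG, OLD),
    (OLD, YOUNG),
    (POOLED, YOUNG),
    (POOLED, OLD),
]


def regime_name(train: str, test: str) -> str:
    return f"{train}:{test}"


def split_median(ages: np.ndarray) -> np.ndarray:
    """Label subjects 'young' (age <= median; ties go young) or 'old'."""
    ages = np.asarray(ages, float)
    if len(ages) < 4:
        raise ValueError("need at least 4 subjects for a median split")
    med = np.median(ages)
    if ages.min() == ages.max():
        raise ValueError("constant ages: median split undefined")
    return np.where(ages <= med, YOUNG, OLD)


@dataclass
class FoldPlan:
    """Repeated k-fold test-fold assignments per age group, shared across regimes."""

    k: int
    repeats: int
    group_rows: dict[str, np.ndarray]  # group -> cohort row indices
    fold_ids: dict[str, np.ndarray]  # group -> (repeats, n_group) fold labels

    def test_rows(self, group: str, repeat: int, fold: int) -> np.ndarray:
        rows = self.group_rows[group]
        return rows[self.fold_ids[group][repeat] == fold]

    def train_rows(self, group: str, repeat: int, fold: int) -> np.ndarray:
        rows = self.group_rows[group]
        return rows[self.fold_ids[group][repeat] != fold]


def make_fold_plan(
    group_labels: np.ndarray, k: int = 10, repeats: int = 10, seed: int = 0
) -> FoldPlan:
    """Independent random k-way partition of each group, per repetition."""
    group_labels = np.asarray(group_labels)
    rng = substream(seed, "fold-plan")
    group_rows: dict[str, np.ndarray] = {}
    fold_ids: dict[str, np.ndarray] = {}
    for group in (YOUNG, OLD):
        rows = np.where(group_labels == group)[0]
        n = len(rows)
        if n < k:
            raise ValueError(f"group '{group}' has {n} subjects, fewer than k={k}")
        group_rows[group] = rows
        ids = np.empty((repeats, n), dtype=int)
        base = np.arange(n) % k  # balanced fold sizes
        for rep in range(repeats):
            ids[rep] = base[rng.permutation(n)]
        fold_ids[group] = ids
    return FoldPlan(k=k, repeats=repeats, group_rows=group_rows, fold_ids=fold_ids)


def subsample_pooled(pool: np.ndarray, target_n: int, seed: int) -> np.ndarray:
    """Uniform random subset of ``pool`` without replacement, size ``target_n``."""
    pool = np.asarray(pool)
    if target_n > len(pool):
        raise ValueError(f"target_n={target_n} exceeds pool size {len(pool)}")
    rng = substream(seed, "pooled-subsample")
    return rng.choice(pool, size=target_n, replace=False)


@dataclass
class ElasticNetSpec:
    """Hyperparameter grid and, after fitting, the selected model."""

    alpha_grid: np.ndarray = field(default_factory=lambda: np.logspace(-3, 2, 13))
    rho_grid: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 0.75, 1.0)
    inner_folds: int = 5
    max_iter: int = 2000
    alpha: float | None = None
    rho: float | None = None
    coef: np.ndarray | None = None
    intercept: float | None = None


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    rho: float,
    fit_intercept: bool = True,
    tol: float = 1e-6,
    max_iter: int = 50000,
) -> ElasticNet:
    """Single elastic net fit at fixed (alpha, rho) on the scikit-learn objective."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = ElasticNet(
            alpha=alpha, l1_ratio=rho, fit_intercept=fit_intercept, tol=tol, max_iter=max_iter
        )
        model.fit(np.asarray(X, float), np.asarray(y, float))
    return model


def train_elastic_net_nested(
    X: np.ndarray, y: np.ndarray, spec: ElasticNetSpec, seed: int = 0
) -> ElasticNetSpec:
    """Select (alpha, rho) by inner-CV mean squared error and refit on all rows.

    X must already be standardized on these training rows; y deconfounded.
    """
    if len(spec.alpha_grid) == 0 or len(spec.rho_grid) == 0:
        raise ValueError("empty hyperparameter grid")
    inner = KFold(n_splits=spec.inner_folds, shuffle=True, random_state=int(seed) % (2**31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = ElasticNetCV(
            alphas=np.asarray(spec.alpha_grid, float),
            l1_ratio=list(spec.rho_grid),
            cv=inner,
            max_iter=spec.max_iter,
            n_jobs=None,
        )
        model.fit(np.asarray(X, float), np.asarray(y, float))
    return replace(
        spec,
        alpha=float(model.alpha_),
        rho=float(model.l1_ratio_),
        coef=model.coef_.copy(),
        intercept=float(model.intercept_),
    )


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Pearson r, RMSE and %dRMSE against the mean-predictor null.

    RMSE_null is the population SD of the observed test target, the error a
    naive mean predictor cannot reduce; %dRMSE = 100 (1 - RMSE/RMSE_null).
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if len(y_true) < 3:
        raise ValueError("need at least 3 observations")
    sd = y_true.std()
    if sd <= 0:
        raise ValueError("constant test target: correlation undefined")
    if np.std(y_pred) > 0:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    else:
        r = 0.0  # degenerate constant prediction carries no linear association
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return {"r": r, "rmse": rmse, "rmse_null": float(sd),
            "pct_delta_rmse": float(100.0 * (1.0 - rmse / sd))}


def fisher_z_mean(rs) -> float:
    """Average correlations on the atanh scale and back-transform."""
    rs = np.clip(np.asarray(rs, float), -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.arctanh(rs).mean()))


# ---------------------------------------------------------------------------
# the six-regime generalization experiment
# ---------------------------------------------------------------------------


def _prepare_fold(cohort, train_rows, test_rows, variance_threshold, K, trait_order):
    """Fit impute -> deconfound -> composite -> standardize on training rows only.

    Returns (X_train, y_train, X_test, y_test, artifacts).  ``artifacts``
    carries every training-time object so leakage can be audited.
    """
    ess, nuis = cohort.essential, cohort.nuisance
    e_tr, n_tr = ess.iloc[train_rows], nuis.iloc[train_rows]
    e_te, n_te = ess.iloc[test_rows], nuis.iloc[test_rows]

    X_tr, idp_means = impute_mean(cohort.idps.iloc[train_rows])
    X_te, _ = impute_mean(cohort.idps.iloc[test_rows], idp_means)

    design = build_confound_design(e_tr, n_tr, variance_threshold)
    dm_idp = fit_deconfound(design, e_tr, n_tr, X_tr)
    Xr_tr = apply_deconfound(dm_idp, e_tr, n_tr, X_tr)
    Xr_te = apply_deconfound(dm_idp, e_te, n_te, X_te)

    traits = cohort.traits[trait_order]
    dm_tr = fit_deconfound(design, e_tr, n_tr, traits.iloc[train_rows])
    Tr_tr = pd.DataFrame(
        apply_deconfound(dm_tr, e_tr, n_tr, traits.iloc[train_rows]), columns=trait_order
    )
    Tr_te = pd.DataFrame(
        apply_deconfound(dm_tr, e_te, n_te, traits.iloc[test_rows]), columns=trait_order
    )
    spec, y_tr = build_composite(Tr_tr, K=K)
    y_te = apply_composite(spec, Tr_te)

    mu, sd = Xr_tr.mean(axis=0), Xr_tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    artifacts = {
        "idp_means": idp_means, "design": design, "deconfound_idp": dm_idp,
        "deconfound_traits": dm_tr, "composite": spec, "x_mean": mu, "x_scale": sd,
    }
    return (Xr_tr - mu) / sd, y_tr, (Xr_te - mu) / sd, y_te, artifacts


def run_generalization(
    cohort,
    plan: FoldPlan,
    enet: ElasticNetSpec | None = None,
    variance_threshold: float = 0.85,
    K: int | None = None,
    trait_order: list[str] | None = None,
    seed: int = 0,
    keep_coefs: bool = True,
) -> dict:
    """Run the six train/test regimes over the full fold plan.

    Returns a dict with ``fold_log`` (one row per repetition x regime x
    fold), ``outcomes`` (per repetition x regime, fold r values Fisher-z
    averaged), and ``coefs`` (fitted coefficient vectors per fold, for the
    per-category summaries).
    """
    enet = enet or ElasticNetSpec()
    trait_order = trait_order or list(cohort.traits.columns)
    if cohort.traits[trait_order].isna().any().any():
        raise ValueError(
            "traits used for the composite contain missing values; exclude those subjects first"
        )
    K = K or len(trait_order)
    seed_rng = substream(seed, "generalization-fits")

    records = []
    coef_records = []
    for rep in range(plan.repeats):
        for fold in range(plan.k):
            for train_g, test_g in REGIMES:
                test_rows = plan.test_rows(test_g, rep, fold)
                target_n = len(plan.train_rows(test_g, rep, fold))
                if train_g == POOLED:
                    pool = np.concatenate(
                        [plan.train_rows(YOUNG, rep, fold), plan.train_rows(OLD, rep, fold)]
                    )
                    sub_seed = int(seed_rng.integers(2**31))
                    train_rows = np.sort(subsample_pooled(pool, target_n, sub_seed))
                else:
                    train_rows = plan.train_rows(train_g, rep, fold)
                X_tr, y_tr, X_te, y_te, _ = _prepare_fold(
                    cohort, train_rows, test_rows, variance_threshold, K, trait_order
                )
                fit_seed = int(seed_rng.integers(2**31))
                fitted = train_elastic_net_nested(X_tr, y_tr, enet, seed=fit_seed)
                y_pred = X_te @ fitted.coef + fitted.intercept
                metrics = evaluate_predictions(y_te, y_pred)
                records.append({
                    "repeat": rep, "fold": fold, "train": train_g, "test": test_g,
                    "regime": regime_name(train_g, test_g),
                    "n_train": len(train_rows), "n_test": len(test_rows),
                    "alpha": fitted.alpha, "rho": fitted.rho, **metrics,
                })
                if keep_coefs:
                    coef_records.append({
                        "repeat": rep, "fold": fold, "train": train_g, "test": test_g,
                        "coef": fitted.coef,
                    })

    fold_log = pd.DataFrame(records)
    grouped = fold_log.groupby(["repeat", "regime"], sort=True)
    outcomes = grouped.agg(
        train=("train", "first"),
        test=("test", "first"),
        r=("r", fisher_z_mean),
        rmse=("rmse", "mean"),
        pct_delta_rmse=("pct_delta_rmse", "mean"),
        alpha_mean=("alpha", "mean"),
        alpha_median=("alpha", "median"),
        rho_mean=("rho", "mean"),
        rho_median=("rho", "median"),
    ).reset_index()
    return {"fold_log": fold_log, "outcomes": outcomes, "coefs": coef_records}


# ---------------------------------------------------------------------------
# regime comparisons
# ---------------------------------------------------------------------------

#: Planned contrasts: the three strategy-level comparisons and the two
#: young-trained vs old-trained comparisons within each test group.
PLANNED_CONTRASTS: list[tuple[str, str]] = [
    ("within", "pooled"),
    ("within", "across"),
    ("pooled", "across"),
    ("young:young", "old:young"),
    ("young:old", "old:old"),
]

_STRATEGY = {
    "within": [regime_name(YOUNG, YOUNG), regime_name(OLD, OLD)],
    "across": [regime_name(YOUNG, OLD), regime_name(OLD, YOUNG)],
    "pooled": [regime_name(POOLED, YOUNG), regime_name(POOLED, OLD)],
}


def _per_repeat_series(outcomes: pd.DataFrame, unit: str) -> np.ndarray:
    """Per-repetition accuracy for a regime ('train:test') or strategy aggregate."""
    wide = outcomes.pivot(index="repeat", columns="regime", values="r").sort_index()
    if unit in wide.columns:
        return wide[unit].to_numpy(float)
    if unit in _STRATEGY:
        cols = _STRATEGY[unit]
        return np.array([fisher_z_mean(row) for row in wide[cols].to_numpy(float)])
    raise KeyError(f"unknown comparison unit: {unit}")


def compare_regimes(
    outcomes: pd.DataFrame, contrasts: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank comparisons of per-repetition accuracies.

    Differences are taken per matched repetition; zeros are dropped (Wilcoxon
    convention) and the exact two-sided null distribution is used for n <= 25.
    BH correction runs across the planned contrast set.
    """
    contrasts = contrasts or PLANNED_CONTRASTS
    reps = outcomes.groupby("regime")["repeat"].nunique()
    if reps.nunique() != 1:
        raise ValueError("unmatched repetitions across regimes")
    rows = []
    for a, b in contrasts:
        va, vb = _per_repeat_series(outcomes, a), _per_repeat_series(outcomes, b)
        d = va - vb
        nz = d[d != 0]
        if len(nz) == 0:
            stat, p = np.nan, 1.0
        else:
            method = "exact" if len(nz) <= 25 else "auto"
            try:
                res = stats.wilcoxon(nz, alternative="two-sided", method=method)
            except ValueError:
                res = stats.wilcoxon(nz, alternative="two-sided", method="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        se = d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else np.nan
        rows.append({
            "contrast": f"{a} vs {b}", "a": a, "b": b,
            "mean_delta_r": float(d.mean()),
            "ci95_low": float(d.mean() - 1.96 * se) if np.isfinite(se) else np.nan,
            "ci95_high": float(d.mean() + 1.96 * se) if np.isfinite(se) else np.nan,
            "wilcoxon_stat": stat, "p": p, "n_pairs": int(len(d)), "n_nonzero": int(len(nz)),
        })
    frame = pd.DataFrame(rows)
    frame["p_bh"] = bh_adjust(frame["p"].to_numpy())
    return frame


def summarize_coefficients_by_category(
    coefs: np.ndarray, categories, idp_names: list[str] | None = None
) -> pd.Series:
    """Mean absolute coefficient per IDP category, averaged over models.

    ``coefs`` is (n_models, n_idps) or a single coefficient vector;
    ``categories`` gives the category label of each IDP column.
    """
    B = np.atleast_2d(np.asarray(coefs, float))
    cats = pd.Series(list(categories))
    if len(cats) != B.shape[1]:
        raise ValueError(
            f"category labels ({len(cats)}) do not align with coefficients ({B.shape[1]})"
        )
    mean_abs = pd.Series(np.abs(B).mean(axis=0))
    out = mean_abs.groupby(cats.values).mean()
    out.index.name = "category"
    return out


def relative_reduction(reference: float, other: float) -> float:
    """Percent reduction of ``other`` relative to ``reference``: 100 (1 - other/reference)."""
    if reference == 0:
        raise ValueError("reference mean coefficient is zero")
    return float(100.0 * (1.0 - other / reference))
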