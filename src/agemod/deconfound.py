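"""Confound design construction and leakage-safe linear deconfounding.

A small set of essential confounds (age, sex, age x sex, site, head size,
motion, ...) enters the design untouched; the remaining large nuisance block
is z-scored with training statistics and compressed by PCA, retaining the
smallest number of components whose cumulative explained variance strictly
exceeds a threshold (default 0.85).  Variables (IDPs and cognitive traits)
are then residualised on the design by per-variable OLS with intercept.

Two fitting modes mirror how the design is used downstream: ``full`` fits
the design and regressions once on all subjects (univariate analyses);
``fold`` fits them on each training fold and applies the frozen
transformation to held-out rows (cross-validated analyses), so no test-set
statistic ever leaks into training.  Held-out residuals are therefore not
exactly orthogonal to held-out confounds -- that is the contract, not a bug.

A control mode drops every age-related column (any design column whose name
contains "age", including age^2 and age x sex nuisance terms) to reproduce
the no-age-deconfounding control analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConfoundDesign",
    "DeconfoundModel",
    "build_confound_design",
    "fit_deconfound",
    "apply_deconfound",
    "impute_mean",
    "is_age_related",
]


def is_age_related(name: str) -> bool:
    """A design column is age-related if its name contains 'age' (age, age_x_sex, nuis_age_sq, ...)."""
    return "age" in name.lower()


@dataclass
class ConfoundDesign:
    """Essential confound columns plus a PCA compression of the nuisance block.

    All statistics (nuisance means/scales, PCA loadings) come from the rows
    the design was built on, so the same design can be applied to new rows
    without touching their data.
    """

    essential_names: list[str]
    nuisance_names: list[str]  # nuisance columns actually used (post age filtering)
    nuisance_mean: np.ndarray
    nuisance_scale: np.ndarray
    nuisance_loadings: np.ndarray  # (n_nuisance_used, n_retained)
    n_retained: int
    variance_threshold: float
    explained_variance: float
    age_terms: bool = True
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.essential_names) + self.n_retained

    def matrix(self, essential: pd.DataFrame, nuisance: pd.DataFrame) -> np.ndarray:
        """Design matrix [essential | nuisance PC scores] for the given rows."""
        missing = [c for c in self.essential_names if c not in essential.columns]
        missing += [c for c in self.nuisance_names if c not in nuisance.columns]
        if missing:
            raise ValueError(f"confound columns missing from input: {missing}")
        E = essential[self.essential_names].to_numpy(float)
        if self.n_retained == 0:
            return E
        N = nuisance[self.nuisance_names].to_numpy(float)
        Z = (N - self.nuisance_mean) / self.nuisance_scale
        return np.column_stack([E, Z @ self.nuisance_loadings])

    def to_dict(self) -> dict:
        return {
            "essential_names": list(self.essential_names),
            "nuisance_names": list(self.nuisance_names),
            "nuisance_mean": self.nuisance_mean.tolist(),
            "nuisance_scale": self.nuisance_scale.tolist(),
            "nuisance_loadings": self.nuisance_loadings.tolist(),
            "n_retained": self.n_retained,
            "variance_threshold": self.variance_threshold,
            "explained_variance": self.explained_variance,
            "age_terms": self.age_terms,
            "dropped_columns": list(self.dropped_columns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConfoundDesign":
        return cls(
            essential_names=list(d["essential_names"]),
            nuisance_names=list(d["nuisance_names"]),
            nuisance_mean=np.asarray(d["nuisance_mean"], float),
            nuisance_scale=np.asarray(d["nuisance_scale"], float),
            nuisance_loadings=np.asarray(d["nuisance_loadings"], float),
            n_retained=int(d["n_retained"]),
            variance_threshold=float(d["variance_threshold"]),
            explained_variance=float(d["explained_variance"]),
            age_terms=bool(d["age_terms"]),
            dropped_columns=list(d["dropped_columns"]),
        )


def build_confound_design(
    essential: pd.DataFrame,
    nuisance: pd.DataFrame,
    variance_threshold: float = 0.85,
    age_terms: bool = True,
) -> ConfoundDesign:
    """Build the reduced confound design from training rows.

    Nuisance columns are centred and scaled with training statistics and
    eigen-decomposed; the smallest component count whose cumulative explained
    variance strictly exceeds ``variance_threshold`` is retained.  Essential
    columns pass through untouched.  With ``age_terms=False`` every
    age-related column (essential or nuisance) is dropped first.
    """
    if not 0.0 < variance_threshold < 1.0:
        raise ValueError("variance_threshold must lie in (0, 1)")
    if len(essential) != len(nuisance):
        raise ValueError("essential and nuisance tables must be row-aligned")

    ess_names = list(essential.columns)
    nuis_names = list(nuisance.columns)
    dropped: list[str] = []
    if not age_terms:
        dropped = [c for c in ess_names + nuis_names if is_age_related(c)]
        ess_names = [c for c in ess_names if not is_age_related(c)]
        nuis_names = [c for c in nuis_names if not is_age_related(c)]

    n = len(nuisance)
    m = len(nuis_names)
    if m == 0:
        return ConfoundDesign(
            essential_names=ess_names,
            nuisance_names=[],
            nuisance_mean=np.empty(0),
            nuisance_scale=np.empty(0),
            nuisance_loadings=np.empty((0, 0)),
            n_retained=0,
            variance_threshold=variance_threshold,
            explained_variance=1.0,
            age_terms=age_terms,
            dropped_columns=dropped,
        )

    N = nuisance[nuis_names].to_numpy(float)
    mean = N.mean(axis=0)
    scale = N.std(axis=0)
    scale[scale <= 0] = 1.0  # constant columns carry no variance
    Z = (N - mean) / scale

    if n <= m:
        logger.warning(
            "fewer subjects (%d) than nuisance columns (%d); PCA is rank-truncated", n, m
        )
    # eigendecomposition of the training covariance via SVD (rank-safe)
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    var = svals**2 / n
    total = var.sum()
    cum = np.cumsum(var) / total
    k = int(np.searchsorted(cum, variance_threshold, side="right") + 1)
    k = min(k, len(var))
    return ConfoundDesign(
        essential_names=ess_names,
        nuisance_names=nuis_names,
        nuisance_mean=mean,
        nuisance_scale=scale,
        nuisance_loadings=vt[:k].T,
        n_retained=k,
        variance_threshold=variance_threshold,
        explained_variance=float(cum[k - 1]),
        age_terms=age_terms,
        dropped_columns=dropped,
    )


@dataclass
class DeconfoundModel:
    """Per-variable OLS coefficients of variables on the confound design."""

    design: ConfoundDesign
    coef: np.ndarray  # (n_design_columns + 1, n_variables); row 0 = intercept
    variable_names: list[str]

    def to_dict(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "coef": self.coef.tolist(),
            "variable_names": list(self.variable_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeconfoundModel":
        return cls(
            design=ConfoundDesign.from_dict(d["design"]),
            coef=np.asarray(d["coef"], float),
            variable_names=list(d["variable_names"]),
        )


def fit_deconfound(
    design: ConfoundDesign,
    essential: pd.DataFrame,
    nuisance: pd.DataFrame,
    variables: pd.DataFrame | np.ndarray,
) -> DeconfoundModel:
    """Fit per-variable OLS (with intercept) of the variables on the design.

    Variables must be complete (impute first).  A rank-deficient design falls
    back to the minimum-norm least-squares solution with a logged warning.
    """
    D = design.matrix(essential, nuisance)
    if isinstance(variables, pd.DataFrame):
        names = list(variables.columns)
        V = variables.to_numpy(float)
    else:
        V = np.asarray(variables, float)
        if V.ndim == 1:
            V = V[:, None]
        names = [f"var_{j}" for j in range(V.shape[1])]
    if np.isnan(V).any():
        raise ValueError("variables contain missing values; impute before deconfounding")
    if len(D) != len(V):
        raise ValueError("design and variables must be row-aligned")
    A = np.column_stack([np.ones(len(D)), D])
    coef, _, rank, _ = np.linalg.lstsq(A, V, rcond=None)
    if rank < A.shape[1]:
        logger.warning(
            "rank-deficient confound design (rank %d < %d columns); using minimum-norm solution",
            rank, A.shape[1],
        )
    return DeconfoundModel(design=design, coef=coef, variable_names=names)


def apply_deconfound(
    model: DeconfoundModel,
    essential: pd.DataFrame,
    nuisance: pd.DataFrame,
    variables: pd.DataFrame | np.ndarray,
) -> np.ndarray:
    """Residualise variables on the frozen confound model: V - [1 | D] coef."""
    D = model.design.matrix(essential, nuisance)
    V = variables.to_numpy(float) if isinstance(variables, pd.DataFrame) else np.asarray(variables, float)
    if V.ndim == 1:
        V = V[:, None]
    if V.shape[1] != model.coef.shape[1]:
        raise ValueError(
            f"variable count mismatch: model has {model.coef.shape[1]}, input has {V.shape[1]}"
        )
    A = np.column_stack([np.ones(len(D)), D])
    return V - A @ model.coef


def impute_mean(
    values: pd.DataFrame | np.ndarray, reference_means: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaN entries by per-column reference means.

    ``reference_means`` defaults to the column means of the observed entries
    of ``values`` itself (full-cohort mode); in cross-validation contexts the
    means must come from the training rows only.  Returns (imputed matrix,
    column means used).  A column with no mean available raises.
    """
    V = values.to_numpy(float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    V = V.copy()
    if reference_means is None:
        observed = (~np.isnan(V)).sum(axis=0)
        sums = np.nansum(V, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            reference_means = np.where(observed > 0, sums / np.maximum(observed, 1), np.nan)
    reference_means = np.asarray(reference_means, float)
    if reference_means.shape != (V.shape[1],):
        raise ValueError("reference_means length must match the column count")
    if np.isnan(reference_means).any():
        bad = np.where(np.isnan(reference_means))[0]
        raise ValueError(f"no observed training values to impute columns {bad.tolist()}")
    mask = np.isnan(V)
    V[mask] = np.broadcast_to(reference_means, V.shape)[mask]
    return V, reference_means
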