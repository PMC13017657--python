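"""Composite cognitive target construction.

Individual cognitive traits are noisy and unevenly covered, so the analysis
target is a composite: traits are screened for data coverage, ranked by how
well an elastic net predicts them from the IDPs (cross-validated Pearson r),
and the top K (default 30) are z-scored and combined by PCA, the first
principal component serving as the cognitive target.  The PCA loadings,
training means/scales and a sign convention are frozen in a CompositeSpec so
the identical transformation can be applied to held-out subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from ._rng import substream

__all__ = [
    "CompositeSpec",
    "screen_and_rank_traits",
    "build_composite",
    "apply_composite",
]

# hyperparameter grid shared with the cross-age prediction stage
DEFAULT_ALPHA_GRID = np.logspace(-3, 2, 13)
DEFAULT_RHO_GRID = (0.0, 0.1, 0.25, 0.5, 0.75, 1.0)


@dataclass
class CompositeSpec:
    """Frozen recipe turning selected trait scores into one composite score."""

    selected_traits: list[str]
    trait_means: np.ndarray
    trait_scales: np.ndarray
    pc_loadings: np.ndarray  # unit Euclidean norm
    sign: float  # +1/-1, fixes the arbitrary PC orientation
    explained_variance_fraction: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_traits": list(self.selected_traits),
                "trait_means": self.trait_means.tolist(),
                "trait_scales": self.trait_scales.tolist(),
                "pc_loadings": self.pc_loadings.tolist(),
                "sign": self.sign,
                "explained_variance_fraction": self.explained_variance_fraction,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CompositeSpec":
        d = json.loads(text)
        return cls(
            selected_traits=list(d["selected_traits"]),
            trait_means=np.asarray(d["trait_means"], float),
            trait_scales=np.asarray(d["trait_scales"], float),
            pc_loadings=np.asarray(d["pc_loadings"], float),
            sign=float(d["sign"]),
            explained_variance_fraction=float(d["explained_variance_fraction"]),
        )


def screen_and_rank_traits(
    idps: np.ndarray,
    traits: pd.DataFrame,
    coverage_threshold: float = 0.8,
    cv_folds: int = 5,
    alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID,
    inner_folds: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen traits for coverage and rank the survivors by brain predictability.

    Coverage is the fraction of subjects with an observed value.  Each
    surviving trait is scored by the Pearson r between its observed values
    and out-of-sample elastic net predictions from the IDPs (``cv_folds``
    outer folds; hyperparameters selected per fold on the inner grid).
    Returns a frame sorted by descending score, ties broken by trait name.
    """
    X_full = np.asarray(idps, float)
    coverage = 1.0 - traits.isna().mean(axis=0)
    survivors = sorted(coverage.index[coverage >= coverage_threshold])
    if not survivors:
        raise ValueError(
            f"no trait reaches coverage {coverage_threshold}; max is {coverage.max():.3f}"
        )
    rng = substream(seed, "trait-screening")
    rows = []
    for name in survivors:
        t = traits[name].to_numpy(float)
        obs = ~np.isnan(t)
        X = X_full[obs]
        y = t[obs]
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        pred = np.empty_like(y)
        for tr, te in kf.split(X):
            mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            model = ElasticNetCV(
                alphas=np.asarray(alpha_grid, float),
                l1_ratio=list(rho_grid),
                cv=inner_folds,
                max_iter=5000,
            )
            model.fit((X[tr] - mu) / sd, y[tr])
            pred[te] = model.predict((X[te] - mu) / sd)
        score = float(np.corrcoef(y, pred)[0, 1]) if np.std(pred) > 0 else 0.0
        rows.append({"trait": name, "coverage": float(coverage[name]), "score": score})
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["score", "trait"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def build_composite(
    traits_train: pd.DataFrame, K: int = 30, ranked: pd.DataFrame | None = None
) -> tuple[CompositeSpec, np.ndarray]:
    """Combine the top-K traits into a first-principal-component composite.

    ``ranked`` (output of :func:`screen_and_rank_traits`) supplies the
    selection order; without it, traits are taken in column order.  Training
    rows must be complete for the selected traits.  Traits are z-scored on
    training statistics (population SD); the leading eigenvector of their
    covariance gives the loadings, oriented so the composite correlates
    positively with the mean standardized trait.
    """
    if ranked is not None:
        order = list(ranked["trait"])
    else:
        order = list(traits_train.columns)
    if K > len(order):
        raise ValueError(f"K={K} exceeds the {len(order)} available traits")
    selected = order[:K]
    T = traits_train[selected].to_numpy(float)
    if np.isnan(T).any():
        raise ValueError("selected traits contain missing values on training rows")
    means = T.mean(axis=0)
    scales = T.std(axis=0)
    if np.any(scales <= 0):
        bad = [selected[j] for j in np.where(scales <= 0)[0]]
        raise ValueError(f"constant traits cannot enter the composite: {bad}")
    Z = (T - means) / scales
    cov = (Z.T @ Z) / len(Z)
    evals, evecs = np.linalg.eigh(cov)  # ascending; last is the leading PC
    loadings = evecs[:, -1]
    loadings = loadings / np.linalg.norm(loadings)
    scores = Z @ loadings
    mean_trait = Z.mean(axis=1)
    corr = float(np.corrcoef(scores, mean_trait)[0, 1]) if np.std(scores) > 0 else 0.0
    sign = -1.0 if corr < 0 else 1.0
    spec = CompositeSpec(
        selected_traits=selected,
        trait_means=means,
        trait_scales=scales,
        pc_loadings=loadings,
        sign=sign,
        explained_variance_fraction=float(evals[-1] / evals.sum()),
    )
    return spec, sign * scores


def apply_composite(spec: CompositeSpec, traits_new: pd.DataFrame) -> np.ndarray:
    """Score new rows with a frozen CompositeSpec (training means/scales/loadings)."""
    missing = [t for t in spec.selected_traits if t not in traits_new.columns]
    if missing:
        raise ValueError(f"missing selected trait columns: {missing}")
    T = traits_new[spec.selected_traits].to_numpy(float)
    if np.isnan(T).any():
        raise ValueError("selected traits contain missing values")
    Z = (T - spec.trait_means) / spec.trait_scales
    return spec.sign * (Z @ spec.pc_loadings)
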