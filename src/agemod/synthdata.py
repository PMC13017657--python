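"""Synthetic cohort generator.

Emulates the statistical structure of a large ageing-cohort imaging study:
ages spanning mid-to-late adulthood, a block of essential confounds (age,
sex, age x sex, site, head size, motion, ...), a correlated low-rank nuisance
confound block that includes further age-related terms (age^2, age x sex), a
matrix of structural imaging-derived phenotypes (IDPs) organised in
categories, and a set of cognitive trait scores loading on a shared latent
factor.  The generative law supports age-quartile-dependent IDP->cognition
slopes (moderation) and optionally inflated residual noise in the older half
of the cohort, which are exactly the effects the downstream analyses are
designed to detect.

Every cohort carries its ground-truth generative parameters so recovery can
be tested without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .unimod import assign_age_quartiles

__all__ = [
    "DEFAULT_IDP_CATEGORY_SIZES",
    "CohortConfig",
    "GenerativeTruth",
    "Cohort",
    "make_moderation_profile",
    "apply_missingness",
    "generate_cohort",
    "scaled_category_sizes",
    "null_moderation_config",
    "moderated_cohort_config",
    "asymmetric_generalization_config",
]

#: Structural IDP category composition of a full-scale cohort: regional and
#: tissue volume, cortical area, cortical thickness, regional and tissue
#: intensity, gray-white contrast, white-matter hyperintensity volume and
#: T2-weighted measures (1439 IDPs in total).
DEFAULT_IDP_CATEGORY_SIZES: dict[str, int] = {
    "volume": 646,
    "area": 372,
    "thickness": 306,
    "intensity": 41,
    "contrast": 70,
    "t2": 3,
    "wmh": 1,
}


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generative model.

    Defaults mirror the full-scale study conditions (age span 47-83 years,
    17 essential + 545 nuisance confounds, 1439 IDPs in seven categories,
    30 cognitive traits, 2.17% IDP missingness).  Smaller analyses override
    the counts explicitly.
    """

    n_subjects: int = 25170
    age_range: tuple[float, float] = (47.0, 83.0)
    n_essential_confounds: int = 17
    n_nuisance_confounds: int = 545
    idp_category_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_IDP_CATEGORY_SIZES)
    )
    trait_count: int = 30
    #: Correlation of each trait with the shared latent cognitive factor.
    #: None -> loadings spread over [0.7, 0.25] across traits.
    trait_loading_profile: np.ndarray | None = None
    #: Linear age trend of each trait (on the z-scored age scale).
    trait_age_slope: float = -0.3
    #: Per-IDP, per-quartile latent-factor slope matrix (n_idps x 4).
    #: None -> constant base_slope everywhere (no moderation).
    moderation_profile: np.ndarray | None = None
    base_slope: float = 0.15
    idp_noise_sd: float = 1.0
    #: Ratio of old-half to young-half residual SD.  Applied to trait
    #: residuals by default (noise_target="traits"); set "idps" to inflate
    #: IDP residual noise instead, or "both" for both.
    group_noise_ratio: float = 1.0
    noise_target: str = "traits"
    idp_missing_rate: float = 0.0217
    trait_missing_rate: float = 0.0
    age_dependent_missingness: bool = False
    n_nuisance_factors: int = 5
    seed: int = 0

    @property
    def n_idps(self) -> int:
        return int(sum(self.idp_category_sizes.values()))

    def validate(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError("age_range: low must be strictly less than high")
        for name in ("n_subjects", "n_essential_confounds", "trait_count"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be >= 1")
        if self.n_nuisance_confounds < 0:
            raise ConfigError("n_nuisance_confounds: must be >= 0")
        for cat, size in self.idp_category_sizes.items():
            if size < 1:
                raise ConfigError(f"idp_category_sizes[{cat!r}]: must be >= 1")
        for name in ("idp_missing_rate", "trait_missing_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name}: must lie in [0, 1]")
        if not self.group_noise_ratio > 0:
            raise ConfigError("group_noise_ratio: must be > 0")
        if self.noise_target not in ("traits", "idps", "both"):
            raise ConfigError("noise_target: must be 'traits', 'idps' or 'both'")
        if self.trait_loading_profile is not None:
            load = np.asarray(self.trait_loading_profile, float)
            if load.shape != (self.trait_count,):
                raise ConfigError("trait_loading_profile: length must equal trait_count")
            if np.any(np.abs(load) > 1):
                raise ConfigError("trait_loading_profile: loadings must lie in [-1, 1]")
        if self.moderation_profile is not None:
            prof = np.asarray(self.moderation_profile, float)
            if prof.shape != (self.n_idps, 4):
                raise ConfigError("moderation_profile: shape must be (n_idps, 4)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("trait_loading_profile", "moderation_profile"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        d["age_range"] = list(d["age_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["age_range"] = tuple(d["age_range"])
        for key in ("trait_loading_profile", "moderation_profile"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], float)
        return cls(**d)


@dataclass
class GenerativeTruth:
    """Ground-truth parameters and latent draws behind a synthetic cohort."""

    latent_factor: np.ndarray  # per-subject latent cognitive score
    quartile_slopes: np.ndarray  # (n_idps, 4) true IDP->cognition slopes
    essential_loadings: np.ndarray  # (n_essential, n_idps)
    nuisance_factor_loadings: np.ndarray  # (n_factors, n_idps)
    trait_loadings: np.ndarray  # (trait_count,)
    noise_sds: dict[str, float]  # young/old residual SDs for the noise target
    age_cut_points: np.ndarray  # 3 quartile cut ages

    def __post_init__(self) -> None:
        if self.quartile_slopes.ndim != 2 or self.quartile_slopes.shape[1] != 4:
            raise ValueError("quartile_slopes must have exactly 4 columns")

    def to_dict(self) -> dict:
        return {
            "latent_factor": self.latent_factor.tolist(),
            "quartile_slopes": self.quartile_slopes.tolist(),
            "essential_loadings": self.essential_loadings.tolist(),
            "nuisance_factor_loadings": self.nuisance_factor_loadings.tolist(),
            "trait_loadings": self.trait_loadings.tolist(),
            "noise_sds": dict(self.noise_sds),
            "age_cut_points": self.age_cut_points.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeTruth":
        return cls(
            latent_factor=np.asarray(d["latent_factor"], float),
            quartile_slopes=np.asarray(d["quartile_slopes"], float),
            essential_loadings=np.asarray(d["essential_loadings"], float),
            nuisance_factor_loadings=np.asarray(d["nuisance_factor_loadings"], float),
            trait_loadings=np.asarray(d["trait_loadings"], float),
            noise_sds={k: float(v) for k, v in d["noise_sds"].items()},
            age_cut_points=np.asarray(d["age_cut_points"], float),
        )


@dataclass
class Cohort:
    """A per-subject data bundle: demographics, confounds, IDPs and traits.

    Missing entries in ``idps`` and ``traits`` are encoded as NaN; the
    boolean masks mark them explicitly and always align in shape.
    """

    subjects: pd.DataFrame  # subject_id, age, sex
    essential: pd.DataFrame
    nuisance: pd.DataFrame
    idps: pd.DataFrame
    idp_categories: pd.Series  # idp column name -> category
    traits: pd.DataFrame
    idp_mask: np.ndarray  # True where missing
    trait_mask: np.ndarray
    config: CohortConfig | None = None
    truth: GenerativeTruth | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def ages(self) -> np.ndarray:
        return self.subjects["age"].to_numpy(float)

    def validate(self) -> None:
        if self.subjects["subject_id"].duplicated().any():
            raise ValueError("duplicated subject ids")
        if self.config is not None:
            lo, hi = self.config.age_range
            ages = self.ages
            if ages.min() < lo or ages.max() > hi:
                raise ValueError("ages outside configured range")
        if self.idp_mask.shape != self.idps.shape:
            raise ValueError("idp mask does not align with idp matrix")
        if self.trait_mask.shape != self.traits.shape:
            raise ValueError("trait mask does not align with trait matrix")


def make_moderation_profile(
    n_idps: int,
    base_slope: float,
    quartile_deltas: np.ndarray,
    idp_block: np.ndarray,
) -> np.ndarray:
    """Build an (n_idps, 4) slope matrix: base + per-quartile delta inside
    ``idp_block``, zero slope outside it."""
    deltas = np.asarray(quartile_deltas, float)
    if deltas.shape != (4,):
        raise ValueError("quartile_deltas must be a 4-vector")
    if not (np.isfinite(base_slope) and np.all(np.isfinite(deltas))):
        raise ValueError("base_slope and quartile_deltas must be finite")
    profile = np.zeros((n_idps, 4))
    block = np.asarray(idp_block, int)
    profile[block] = base_slope + deltas
    return profile


def apply_missingness(
    values: np.ndarray,
    rate: float,
    seed: int,
    ages: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Blank entries independently at ``rate``; returns (values-with-NaN, mask).

    By default missingness is completely at random.  If ``ages`` is given,
    per-subject missingness probability ramps linearly with age rank while
    keeping the same mean rate (age-dependent missingness scenario).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"missingness rate must lie in [0, 1], got {rate}")
    values = np.asarray(values, float)
    rng = substream(seed, "missingness")
    if rate == 0.0:
        return values.copy(), np.zeros(values.shape, dtype=bool)
    if ages is None:
        mask = rng.random(values.shape) < rate
    else:
        n = len(ages)
        ranks = np.argsort(np.argsort(ages))
        prob = rate * (0.5 + ranks / max(n - 1, 1))  # mean == rate
        mask = rng.random(values.shape) < np.clip(prob, 0, 1)[:, None]
    out = values.copy()
    out[mask] = np.nan
    return out, mask


def _essential_names(k: int) -> list[str]:
    base = ["age", "sex", "age_x_sex", "site", "head_size", "motion"]
    return (base + [f"ess_{i:02d}" for i in range(len(base), k)])[:k]


def _nuisance_names(k: int) -> list[str]:
    base = ["nuis_age_sq", "nuis_age_x_sex"]
    return (base + [f"nuis_{i:03d}" for i in range(len(base), k)])[:k]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a cohort from the generative model described in the module docstring.

    Deterministic under ``config.seed``: the same configuration always yields
    byte-identical tables.
    """
    config.validate()
    n = config.n_subjects
    p = config.n_idps
    seed = config.seed

    rng_cohort = substream(seed, "cohort")

    lo, hi = config.age_range
    ages = rng_cohort.uniform(lo, hi, size=n)
    # z-scored age under the uniform generative law (known moments)
    age_z = (ages - (lo + hi) / 2) / ((hi - lo) / np.sqrt(12.0))
    sex = rng_cohort.integers(0, 2, size=n).astype(float)

    # --- essential confounds -------------------------------------------------
    e = config.n_essential_confounds
    ess_names = _essential_names(e)
    essential = np.empty((n, e))
    for j, name in enumerate(ess_names):
        if name == "age":
            essential[:, j] = ages
        elif name == "sex":
            essential[:, j] = sex
        elif name == "age_x_sex":
            essential[:, j] = age_z * sex
        elif name == "site":
            essential[:, j] = rng_cohort.integers(0, 3, size=n).astype(float)
        else:
            essential[:, j] = rng_cohort.normal(size=n)

    # --- nuisance confounds: low-rank Gaussian block + age-related terms ----
    m = config.n_nuisance_confounds
    r = config.n_nuisance_factors
    nuis_names = _nuisance_names(m)
    factors = rng_cohort.normal(size=(n, r))
    if m > 0:
        load = rng_cohort.normal(scale=0.5, size=(r, m))
        nuisance = factors @ load + rng_cohort.normal(scale=0.5, size=(n, m))
        for j, name in enumerate(nuis_names):
            if name == "nuis_age_sq":
                nuisance[:, j] = age_z**2
            elif name == "nuis_age_x_sex":
                nuisance[:, j] = age_z * (sex - 0.5)
    else:
        nuisance = np.empty((n, 0))

    # --- latent cognitive factor and traits ----------------------------------
    g = rng_cohort.normal(size=n)
    if config.trait_loading_profile is not None:
        t_load = np.asarray(config.trait_loading_profile, float)
    else:
        t_load = np.linspace(0.7, 0.25, config.trait_count)
    a_age = config.trait_age_slope
    resid_var = np.clip(1.0 - t_load**2 - a_age**2, 1e-6, None)

    median_age = np.median(ages)
    old = ages > median_age
    trait_ratio = config.group_noise_ratio if config.noise_target in ("traits", "both") else 1.0
    idp_ratio = config.group_noise_ratio if config.noise_target in ("idps", "both") else 1.0
    trait_noise_scale = np.where(old, trait_ratio, 1.0)[:, None]

    eps_t = rng_cohort.normal(size=(n, config.trait_count))
    traits = (
        g[:, None] * t_load[None, :]
        + a_age * age_z[:, None]
        + np.sqrt(resid_var)[None, :] * eps_t * trait_noise_scale
    )

    # --- IDPs: confound effects + quartile-dependent latent signal + noise ---
    quart = assign_age_quartiles(ages)
    if config.moderation_profile is not None:
        slopes = np.asarray(config.moderation_profile, float)
    else:
        slopes = np.full((p, 4), config.base_slope)

    ess_load = rng_cohort.normal(scale=0.1, size=(e, p))
    age_idx = ess_names.index("age") if "age" in ess_names else None
    if age_idx is not None:
        # IDPs are strongly age-dependent, as structural measures are in vivo
        ess_load[age_idx] = rng_cohort.normal(loc=-0.4, scale=0.15, size=p)
    fac_load = rng_cohort.normal(scale=0.1, size=(r, p))

    conf_design = np.column_stack([age_z if nm == "age" else essential[:, j]
                                   for j, nm in enumerate(ess_names)])
    idp_noise_scale = np.where(old, idp_ratio, 1.0)[:, None]
    idps = (
        conf_design @ ess_load
        + factors @ fac_load
        + slopes[:, quart.labels].T * g[:, None]
        + config.idp_noise_sd * rng_cohort.normal(size=(n, p)) * idp_noise_scale
    )

    # --- missingness ----------------------------------------------------------
    miss_ages = ages if config.age_dependent_missingness else None
    idps, idp_mask = apply_missingness(idps, config.idp_missing_rate, seed, ages=miss_ages)
    if config.trait_missing_rate > 0:
        rng_tm = substream(seed, "trait-missingness")
        tmask = rng_tm.random(traits.shape) < config.trait_missing_rate
        traits = traits.copy()
        traits[tmask] = np.nan
        trait_mask = tmask
    else:
        trait_mask = np.zeros(traits.shape, dtype=bool)

    # --- assemble tables ------------------------------------------------------
    idp_cols: list[str] = []
    idp_cats: list[str] = []
    for cat, size in config.idp_category_sizes.items():
        for i in range(size):
            idp_cols.append(f"{cat}_{i:04d}")
            idp_cats.append(cat)
    trait_cols = [f"trait_{i:02d}" for i in range(config.trait_count)]
    subject_ids = [f"S{i:06d}" for i in range(n)]

    truth = GenerativeTruth(
        latent_factor=g,
        quartile_slopes=slopes,
        essential_loadings=ess_load,
        nuisance_factor_loadings=fac_load,
        trait_loadings=t_load,
        noise_sds={
            "young": float(config.idp_noise_sd if config.noise_target == "idps" else 1.0),
            "old": float(
                (config.idp_noise_sd if config.noise_target == "idps" else 1.0)
                * config.group_noise_ratio
            ),
        },
        age_cut_points=quart.cut_points,
    )

    cohort = Cohort(
        subjects=pd.DataFrame({"subject_id": subject_ids, "age": ages, "sex": sex}),
        essential=pd.DataFrame(essential, columns=ess_names),
        nuisance=pd.DataFrame(nuisance, columns=nuis_names),
        idps=pd.DataFrame(idps, columns=idp_cols),
        idp_categories=pd.Series(idp_cats, index=idp_cols, name="category"),
        traits=pd.DataFrame(traits, columns=trait_cols),
        idp_mask=idp_mask,
        trait_mask=trait_mask,
        config=config,
        truth=truth,
    )
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# named desk-scale study conditions shared by tests and the analysis scripts
# ---------------------------------------------------------------------------


def scaled_category_sizes(p_total: int) -> dict[str, int]:
    """IDP category sizes proportional to the full-scale composition."""
    full = DEFAULT_IDP_CATEGORY_SIZES
    total = sum(full.values())
    sizes = {cat: max(1, round(p_total * k / total)) for cat, k in full.items()}
    # absorb rounding drift into the largest category
    drift = p_total - sum(sizes.values())
    sizes[max(sizes, key=sizes.get)] += drift
    return sizes


def null_moderation_config(seed: int, n_subjects: int = 2000, n_idps: int = 200) -> CohortConfig:
    """Null cohort for calibration: real brain-cognition signal with constant
    quartile slopes and equal residual noise across age halves, so quartile
    labels are exchangeable and the moderation test's p-values should be
    uniform."""
    return CohortConfig(
        n_subjects=n_subjects,
        n_nuisance_confounds=20,
        idp_category_sizes=scaled_category_sizes(n_idps),
        trait_count=8,
        trait_loading_profile=np.linspace(0.6, 0.3, 8),
        base_slope=0.15,
        group_noise_ratio=1.0,
        seed=seed,
    )


def moderated_cohort_config(
    seed: int,
    n_subjects: int = 8000,
    n_idps: int = 200,
    n_moderated: int = 30,
    q4_delta: float = 0.1,
) -> CohortConfig:
    """Moderated cohort: a +q4_delta oldest-quartile slope increment on the
    first ``n_moderated`` IDPs, on top of a shared base slope elsewhere."""
    cfg = null_moderation_config(seed, n_subjects=n_subjects, n_idps=n_idps)
    profile = np.full((cfg.n_idps, 4), cfg.base_slope)
    profile[:n_moderated] += make_moderation_profile(
        cfg.n_idps, 0.0, np.array([0.0, 0.0, 0.0, q4_delta]), np.arange(n_moderated)
    )[:n_moderated]
    cfg.moderation_profile = profile
    return cfg


def asymmetric_generalization_config(
    seed: int, n_subjects: int = 4000, n_idps: int = 200
) -> CohortConfig:
    """Cross-age generalization cohort: shared young/old signal with the old
    half's residual noise doubled on both traits and IDPs, emulating the
    greater heterogeneity of older brains and cognition.  Per-IDP signal is
    weak (slope 0.05 against unit noise) so that, as in real brain-cognition
    prediction, training-set noise materially limits generalization."""
    return CohortConfig(
        n_subjects=n_subjects,
        n_nuisance_confounds=20,
        idp_category_sizes=scaled_category_sizes(n_idps),
        trait_count=8,
        trait_loading_profile=np.linspace(0.45, 0.2, 8),
        base_slope=0.05,
        group_noise_ratio=2.0,
        noise_target="both",
        seed=seed,
    )
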