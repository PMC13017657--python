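"""Quartile-stratified univariate moderation analysis.

For each imaging-derived phenotype (IDP), a joint linear model with four
age-quartile-specific intercepts and four quartile-specific IDP slopes is
fitted to a (deconfounded) cognitive outcome; IDPs are z-scored within each
quartile so slope magnitudes are comparable across quartiles.  Whether a
quartile's slope differs from the others is tested with a quartile-vs-rest
coefficient contrast calibrated by permuting quartile labels across subjects
(within-quartile standardisation recomputed under each permutation, one
shared label shuffle per replicate across all IDPs).  Per-test inference uses
the +1-corrected permutation p-value and Benjamini-Hochberg FDR across all
IDP x quartile tests; ensemble-level enrichment is summarised per quartile by
a Kolmogorov-Smirnov test against uniformity, Storey's pi0, and a
permutation-calibrated Fisher combination that respects the dependence
between IDP-level tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import substream

__all__ = [
    "QuartileAssignment",
    "QuartileModel",
    "ModerationTestResult",
    "EnrichmentSummary",
    "assign_age_quartiles",
    "zscore_within_group",
    "fit_quartile_model",
    "quartile_contrasts",
    "permutation_moderation_test",
    "bh_adjust",
    "storey_pi0",
    "enrichment_summary",
    "enrichment_by_quartile",
    "coefficient_similarity",
]

N_QUARTILES = 4


@dataclass
class QuartileAssignment:
    """Per-subject age-quartile labels (0..3) and the three age cut points.

    Labels follow age order; ties at a cut point all go to the lower quartile.
    """

    labels: np.ndarray
    cut_points: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        self.cut_points = np.asarray(self.cut_points, float)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=N_QUARTILES)


def assign_age_quartiles(ages: np.ndarray) -> QuartileAssignment:
    """Stratify subjects into four age quartiles at the empirical 25/50/75 percentiles."""
    ages = np.asarray(ages, float)
    n = len(ages)
    if n < 8:
        raise ValueError(f"need at least 8 subjects to form quartiles, got {n}")
    cuts = np.percentile(ages, [25, 50, 75])
    labels = np.searchsorted(cuts, ages, side="left")  # age <= cut -> lower quartile
    sizes = np.bincount(labels, minlength=N_QUARTILES)
    if (sizes < 2).any():
        raise ValueError(f"quartile with fewer than 2 subjects (sizes {sizes.tolist()})")
    return QuartileAssignment(labels=labels, cut_points=cuts)


def zscore_within_group(values: np.ndarray, assignment: QuartileAssignment) -> np.ndarray:
    """Z-score a vector within each quartile (population-SD convention)."""
    values = np.asarray(values, float)
    out = np.empty_like(values)
    for q in range(N_QUARTILES):
        sel = assignment.labels == q
        mu = values[sel].mean()
        sd = values[sel].std()  # ddof=0
        if sd <= 0:
            raise ValueError(f"constant values within quartile {q + 1}; cannot z-score")
        out[sel] = (values[sel] - mu) / sd
    return out


@dataclass
class QuartileModel:
    """Per-IDP quartile-specific intercepts a_q, slopes b_q and contrasts T_q."""

    intercepts: np.ndarray  # (p, 4)
    slopes: np.ndarray  # (p, 4)
    contrasts: np.ndarray  # (p, 4)
    idp_names: list[str] | None = None
    constant_flags: np.ndarray | None = None  # IDPs constant within some quartile

    def to_frame(self) -> pd.DataFrame:
        names = self.idp_names or [f"idp_{j}" for j in range(len(self.slopes))]
        cols = {}
        for q in range(N_QUARTILES):
            cols[f"a_q{q + 1}"] = self.intercepts[:, q]
            cols[f"b_q{q + 1}"] = self.slopes[:, q]
            cols[f"t_q{q + 1}"] = self.contrasts[:, q]
        return pd.DataFrame(cols, index=pd.Index(names, name="idp"))


def quartile_contrasts(b: np.ndarray) -> np.ndarray:
    """Quartile-vs-rest contrast T_q = b_q - mean(b_{q' != q}); rows sum to 0."""
    b = np.asarray(b, float)
    total = b.sum(axis=-1, keepdims=True)
    return (4.0 * b - total) / 3.0


def fit_quartile_model(
    idp: np.ndarray, cog: np.ndarray, assignment: QuartileAssignment
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint OLS of cognition on 4 quartile indicators + 4 indicator x IDP columns.

    The IDP is assumed already z-scored within quartiles.  Returns
    (a_q, b_q, T_q).  The design is block-diagonal over quartiles, so the
    joint fit equals four independent per-quartile simple regressions; the
    explicit 8-column fit is kept as the reference implementation.
    """
    idp = np.asarray(idp, float)
    cog = np.asarray(cog, float)
    n = len(idp)
    X = np.zeros((n, 2 * N_QUARTILES))
    for q in range(N_QUARTILES):
        sel = assignment.labels == q
        if not sel.any():
            raise ValueError(f"empty quartile {q + 1}: singular design")
        X[sel, q] = 1.0
        X[sel, N_QUARTILES + q] = idp[sel]
    beta, *_ = np.linalg.lstsq(X, cog, rcond=None)
    a = beta[:N_QUARTILES]
    b = beta[N_QUARTILES:]
    return a, b, quartile_contrasts(b)


# ---------------------------------------------------------------------------
# vectorised slope engine used by the permutation test
# ---------------------------------------------------------------------------


def _grouped_slopes(
    M: np.ndarray, y: np.ndarray, order: np.ndarray, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Slopes/intercepts of y on within-group z-scored X for one label assignment.

    ``M`` is the precomputed (n, 3p) matrix [X, X^2, X*y]; ``order`` lists the
    subject rows, whose consecutive blocks of ``sizes`` form quartiles 1..4.
    Returns (a, b), each (4, p).  Groups where an IDP is constant get slope 0.
    """
    p = M.shape[1] // 3
    a = np.empty((N_QUARTILES, p))
    b = np.empty((N_QUARTILES, p))
    start = 0
    for q in range(N_QUARTILES):
        rows = order[start : start + sizes[q]]
        start += sizes[q]
        nq = sizes[q]
        S = M[rows].sum(axis=0)
        sy = y[rows].sum()
        sx, sx2, sxy = S[:p], S[p : 2 * p], S[2 * p :]
        mu = sx / nq
        var = sx2 / nq - mu**2
        sd = np.sqrt(np.clip(var, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            bq = (sxy - mu * sy) / (sd * nq)
        bq[~np.isfinite(bq)] = 0.0
        b[q] = bq
        a[q] = sy / nq  # z-scored IDP has zero mean within the group
    return a, b


@dataclass
class ModerationTestResult:
    """Permutation moderation test over all IDPs and quartiles."""

    p_values: np.ndarray  # (p, 4)
    q_values: np.ndarray  # (p, 4), BH across all IDP x quartile tests
    intercepts: np.ndarray  # (p, 4) observed a_q
    slopes: np.ndarray  # (p, 4) observed b_q
    contrasts: np.ndarray  # (p, 4) observed T_q
    n_perm: int
    seed: int
    idp_names: list[str] = field(default_factory=list)
    #: (n_perm, p, 4) per-replicate p-value archive (self-inclusive rank
    #: convention, p >= 1/n_perm), kept for the permutation Fisher test.
    perm_p_archive: np.ndarray | None = None

    def p_frame(self) -> pd.DataFrame:
        names = self.idp_names or [f"idp_{j}" for j in range(len(self.p_values))]
        df = pd.DataFrame(
            self.p_values, columns=[f"p_q{q + 1}" for q in range(N_QUARTILES)],
            index=pd.Index(names, name="idp"),
        )
        for q in range(N_QUARTILES):
            df[f"q_q{q + 1}"] = self.q_values[:, q]
        return df


def permutation_moderation_test(
    idps: np.ndarray,
    cog: np.ndarray,
    assignment: QuartileAssignment,
    n_perm: int = 10000,
    seed: int = 0,
    keep_archive: bool = True,
) -> ModerationTestResult:
    """Test age moderation of every IDP's association with cognition.

    Null replicates permute the quartile labels across subjects (one shared
    shuffle per replicate for all IDPs) and recompute within-quartile
    standardisation and the quartile-vs-rest contrasts under the permuted
    labels.  Two-sided p-values use the +1 correction,
    p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(idps, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(cog, float)
    n, p = X.shape

    M = np.concatenate([X, X * X, X * y[:, None]], axis=1)
    sizes = assignment.group_sizes
    obs_order = np.argsort(assignment.labels, kind="stable")

    a_obs, b_obs = _grouped_slopes(M, y, obs_order, sizes)
    t_obs = quartile_contrasts(b_obs.T)  # (p, 4)

    rng = substream(seed, "moderation-permutations")
    abs_t_perm = np.empty((n_perm, p, N_QUARTILES))
    for bidx in range(n_perm):
        order = rng.permutation(n)
        _, b_perm = _grouped_slopes(M, y, order, sizes)
        abs_t_perm[bidx] = np.abs(quartile_contrasts(b_perm.T))

    abs_t_obs = np.abs(t_obs)
    exceed = (abs_t_perm >= abs_t_obs[None, :, :]).sum(axis=0)
    p_values = (1.0 + exceed) / (1.0 + n_perm)
    q_values = bh_adjust(p_values.ravel()).reshape(p_values.shape)

    archive = None
    if keep_archive:
        # self-inclusive exceedance rank of each replicate among all replicates
        ranks = stats.rankdata(abs_t_perm, method="min", axis=0)
        archive = (n_perm - ranks + 1.0) / n_perm

    return ModerationTestResult(
        p_values=p_values,
        q_values=q_values,
        intercepts=a_obs.T,
        slopes=b_obs.T,
        contrasts=t_obs,
        n_perm=n_perm,
        seed=seed,
        perm_p_archive=archive,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    """Storey estimate of the proportion of true nulls: #{p > lambda} / (m (1-lambda))."""
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie strictly in (0, 1)")
    p = np.asarray(p, float)
    m = p.size
    return float(np.clip((p > lam).sum() / (m * (1.0 - lam)), 0.0, 1.0))


@dataclass
class EnrichmentSummary:
    """Ensemble-level evidence of non-null moderation in one quartile."""

    ks_statistic: float
    ks_p: float
    pi0: float
    storey_lambda: float
    fisher_statistic: float
    fisher_p: float
    n_tests: int
    n_perm: int

    def to_dict(self) -> dict:
        return {
            "ks_statistic": self.ks_statistic,
            "ks_p": self.ks_p,
            "pi0": self.pi0,
            "storey_lambda": self.storey_lambda,
            "fisher_statistic": self.fisher_statistic,
            "fisher_p": self.fisher_p,
            "n_tests": self.n_tests,
            "n_perm": self.n_perm,
        }


def enrichment_summary(
    p_obs: np.ndarray, p_perm_archive: np.ndarray, lam: float = 0.5
) -> EnrichmentSummary:
    """Global enrichment of one quartile's p-values.

    KS tests the observed p-values against Uniform(0,1) (p-values are
    discrete on a 1/(n_perm+1) grid, so KS is approximate for small n_perm);
    pi0 is Storey's estimate at ``lam``; the Fisher statistic -2 sum(log p)
    is calibrated against the same statistic on each permutation replicate's
    p-vector, preserving cross-IDP dependence, with the +1 correction.
    """
    p_obs = np.asarray(p_obs, float)
    if p_obs.size < 10:
        raise ValueError("need at least 10 p-values for enrichment summaries")
    arch = np.asarray(p_perm_archive, float)
    if arch.ndim != 2 or arch.shape[1] != p_obs.size:
        raise ValueError("archive must be (n_perm, m) aligned with p_obs")
    ks = stats.kstest(p_obs, "uniform")
    pi0 = storey_pi0(p_obs, lam)
    f_obs = float(-2.0 * np.log(p_obs).sum())
    f_perm = -2.0 * np.log(arch).sum(axis=1)
    nb = arch.shape[0]
    fisher_p = float((1 + (f_perm >= f_obs).sum()) / (1 + nb))
    return EnrichmentSummary(
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        pi0=pi0,
        storey_lambda=lam,
        fisher_statistic=f_obs,
        fisher_p=fisher_p,
        n_tests=int(p_obs.size),
        n_perm=nb,
    )


def enrichment_by_quartile(
    result: ModerationTestResult, lam: float = 0.5
) -> dict[str, EnrichmentSummary]:
    """Per-quartile enrichment summaries from a moderation test with archive."""
    if result.perm_p_archive is None:
        raise ValueError("moderation test was run without the permutation archive")
    out = {}
    for q in range(N_QUARTILES):
        out[f"Q{q + 1}"] = enrichment_summary(
            result.p_values[:, q], result.perm_p_archive[:, :, q], lam
        )
    return out


def coefficient_similarity(slopes: np.ndarray) -> dict[str, pd.DataFrame]:
    """Quartile-pair similarity of per-IDP slopes.

    Returns 4x4 symmetric tables: Pearson correlation of signed slopes, and
    Pearson and Spearman correlations of absolute slopes (feature-importance
    agreement).  Entries involving a constant column are NaN.
    """
    b = np.asarray(slopes, float)
    if b.ndim != 2 or b.shape[1] != N_QUARTILES:
        raise ValueError("slopes must be (n_idps, 4)")
    if b.shape[0] < 3:
        raise ValueError("need at least 3 IDPs")
    labels = [f"Q{q + 1}" for q in range(N_QUARTILES)]

    def table(values: np.ndarray, method: str) -> pd.DataFrame:
        df = pd.DataFrame(values, columns=labels)
        out = df.corr(method=method)
        # constant columns produce NaN off-diagonal; keep unit diagonal
        np.fill_diagonal(out.values, 1.0)
        return out

    return {
        "pearson_signed": table(b, "pearson"),
        "pearson_abs": table(np.abs(b), "pearson"),
        "spearman_abs": table(np.abs(b), "spearman"),
    }
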