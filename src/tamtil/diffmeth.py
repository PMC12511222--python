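"""Infiltration-associated CpG discovery with moderated t-statistics.

For each CpG, an ordinary least-squares model regresses its beta values on
the measured immune infiltration (continuous, %TCC) with WHO grade as a
treatment-coded covariate to control for confounding between malignancy
grade and immune load.  Residual variances are then shrunk toward a
global prior by the standard empirical-Bayes scaled-F model: with
residual variance s_g^2 on d degrees of freedom and prior (d0, s0^2),

    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)
    t_tilde_g   = beta_hat_g / (se_factor * s_tilde_g)        (df = d0 + d)

The prior is estimated by closed-form method of moments on log s^2
(matching the limma/eBayes hyperparameter estimator).  CpGs are ranked by
moderated t, the top K per direction are selected, and only the
hypomethylated direction (beta falling as infiltration rises, i.e. the
immune-cell-specific unmethylated sites) is passed on to signature
training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignError",
    "ModerationError",
    "CpGFits",
    "ModeratedStats",
    "SelectionResult",
    "build_design",
    "fit_cpg_linear_models",
    "estimate_variance_prior",
    "empirical_bayes_moderation",
    "benjamini_hochberg",
    "rank_and_select",
    "filter_hypomethylated",
]

#: Prior df above this value are treated as "effectively infinite".
D0_CAP = 1e6


class DesignError(ValueError):
    pass


class ModerationError(ValueError):
    pass


def build_design(
    clinical: pd.DataFrame,
    outcome: str = "tam",
    adjust_grade: bool = True,
    extra_covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Design matrix: intercept + infiltration outcome (+ grade dummies).

    ``outcome`` is ``'tam'`` or ``'til'`` and resolves to the
    ``<outcome>_pct`` clinical column.  WHO grade enters as treatment-coded
    dummies with grade 1 as reference; a single-level grade column is
    dropped with a warning.  The outcome column is named ``infiltration``
    and flagged in ``attrs``.
    """
    col = f"{outcome}_pct"
    if col not in clinical.columns:
        raise DesignError(f"clinical table lacks outcome column {col!r}")
    y = pd.to_numeric(clinical[col], errors="raise")
    if y.isna().any():
        missing = clinical.index[y.isna()][0]
        raise DesignError(f"outcome {col!r} missing for sample {missing!r}")

    design = pd.DataFrame({"intercept": 1.0, "infiltration": y.astype(float)},
                          index=clinical.index)
    if adjust_grade:
        if "who_grade" not in clinical.columns:
            raise DesignError("adjust_grade requested but who_grade column absent")
        grades = clinical["who_grade"].astype(int)
        levels = sorted(grades.unique())
        if len(levels) == 1:
            warnings.warn(
                f"single WHO grade level {levels[0]} in cohort; grade covariate dropped",
                stacklevel=2,
            )
        else:
            for g in levels[1:]:
                design[f"grade_{g}"] = (grades == g).astype(float)
    for c in extra_covariates:
        design[c] = pd.to_numeric(clinical[c], errors="raise").astype(float)

    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise DesignError("design matrix is rank deficient")
    design.attrs["outcome"] = "infiltration"
    return design


@dataclass
class CpGFits:
    """Per-CpG OLS results for the infiltration coefficient."""

    cpg_ids: pd.Index
    coef: np.ndarray          # effect of infiltration (%TCC) on beta
    s2: np.ndarray            # residual variance
    se_factor: float          # sqrt((X'X)^-1 [outcome, outcome])
    df_resid: int
    zero_variance: np.ndarray  # CpGs whose s2 was raised to machine eps


def fit_cpg_linear_models(beta: pd.DataFrame, design: pd.DataFrame) -> CpGFits:
    """Vectorised OLS of every CpG on the design matrix.

    Requires a complete matrix (run :func:`tamtil.io.drop_incomplete_cpgs`
    first) whose samples match the design rows.  Residual df is
    ``n_samples - n_columns``.
    """
    if not design.index.equals(beta.columns):
        if set(design.index) != set(beta.columns):
            raise DesignError("beta matrix samples and design rows differ")
        design = design.loc[beta.columns]
    Y = beta.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise DesignError("beta matrix contains missing values; drop incomplete CpGs first")
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise DesignError(f"need more samples ({n}) than design columns ({p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = Y @ X @ xtx_inv                       # (m, p)
    resid = Y - coefs @ X.T
    d = n - p
    s2 = np.einsum("ij,ij->i", resid, resid) / d
    s2 = np.where(s2 < 0, 0.0, s2)
    zero = s2 <= 0
    j = design.columns.get_loc("infiltration")
    return CpGFits(
        cpg_ids=beta.index,
        coef=coefs[:, j],
        s2=s2,
        se_factor=float(np.sqrt(xtx_inv[j, j])),
        df_resid=d,
        zero_variance=zero,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df_resid: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on residual variances.

    Under the hierarchical model s^2 ~ s0^2 * F(d, d0), the log variances
    satisfy closed-form moment equations through di/trigamma functions;
    solving them gives (d0, s0^2).  A non-positive excess variance of
    log s^2 (or an estimate beyond ``D0_CAP``) yields an infinite prior
    df, i.e. full pooling of variances.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.where(s2 <= 0, np.finfo(float).eps, s2)
    if s2.size < 2:
        raise ModerationError("need at least 2 CpGs to estimate the variance prior")
    d = float(df_resid)
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        if d0 > D0_CAP:
            d0 = np.inf
    else:
        d0 = np.inf
    if np.isfinite(d0):
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        s0_sq = np.exp(e_mean)
    return float(d0), float(s0_sq)


@dataclass
class ModeratedStats:
    """Per-CpG moderated statistics plus global prior hyperparameters."""

    table: pd.DataFrame   # coef, s2, s2_post, t, p, p_adj, direction
    d0: float
    s0_sq: float
    df_resid: int

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_resid


def empirical_bayes_moderation(
    fits: CpGFits, d0: float | None = None, s0_sq: float | None = None
) -> ModeratedStats:
    """Shrink residual variances and compute moderated t and p per CpG.

    ``d0``/``s0_sq`` override the estimated prior (``d0=0`` reproduces
    ordinary t; ``d0=inf`` pools every variance to ``s0_sq``).
    Zero-variance CpGs get machine-epsilon variance before estimation and
    are flagged in ``fits.zero_variance``.
    """
    s2 = np.where(fits.s2 <= 0, np.finfo(float).eps, fits.s2)
    if not (s2 > np.finfo(float).eps).any() and d0 is None:
        raise ModerationError("all residual variances are zero; cannot moderate")
    est_d0, est_s0 = estimate_variance_prior(s2, fits.df_resid)
    if d0 is None:
        d0 = est_d0
    if s0_sq is None:
        s0_sq = est_s0
    d0 = float(d0)
    if d0 > D0_CAP:  # effectively infinite prior df: full pooling
        d0 = np.inf

    d = fits.df_resid
    if d0 == 0:
        s2_post = s2
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    t = fits.coef / (fits.se_factor * np.sqrt(s2_post))
    df_total = d0 + d
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {
            "coef": fits.coef,
            "s2": fits.s2,
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "p_adj": benjamini_hochberg(p),
            "direction": np.where(fits.coef > 0, "hyper", "hypo"),
        },
        index=fits.cpg_ids,
    )
    return ModeratedStats(table=table, d0=d0, s0_sq=float(s0_sq), df_resid=d)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SelectionResult:
    """Ranked per-direction CpG lists and the set entering model training."""

    hyper: pd.Index            # top-K by moderated t, descending
    hypo: pd.Index             # top-K by moderated t, ascending
    k_per_direction: int
    padj_threshold: float | None
    stats: ModeratedStats

    @property
    def selected(self) -> pd.Index:
        return self.hyper.union(self.hypo)


def rank_and_select(
    stats: ModeratedStats,
    k_per_direction: int = 300,
    padj_threshold: float | None = None,
) -> SelectionResult:
    """Pick the top-K CpGs per direction by moderated t.

    Ties in t break lexicographically on the CpG id for determinism.  An
    optional ``padj_threshold`` pre-filter restricts ranking to CpGs with
    adjusted p at or below the threshold.
    """
    tab = stats.table
    if len(tab) == 0:
        raise ValueError("no CpG statistics to rank")
    if padj_threshold is not None:
        tab = tab[tab["p_adj"] <= padj_threshold]
    ids = tab.index.to_numpy()
    t = tab["t"].to_numpy()
    asc = np.lexsort((ids, t))           # ascending t, ties by id
    desc = np.lexsort((ids, -t))         # descending t, ties by id
    k = int(k_per_direction)
    return SelectionResult(
        hyper=pd.Index(ids[desc[:k]]),
        hypo=pd.Index(ids[asc[:k]]),
        k_per_direction=k,
        padj_threshold=padj_threshold,
        stats=stats,
    )


def filter_hypomethylated(selection: SelectionResult) -> pd.Index:
    """Keep only hypomethylated-direction CpGs from the hypo-ranked list.

    These are the sites whose beta falls as infiltration rises (negative
    infiltration coefficient) -- the immune-cell-specific unmethylated
    loci that carry the deconvolution signal.  Returns an empty index
    (with a warning) if none qualify.
    """
    coef = selection.stats.table.loc[selection.hypo, "coef"]
    out = selection.hypo[coef.to_numpy() < 0]
    if len(out) == 0:
        warnings.warn("no hypomethylated CpGs among the selected set", stacklevel=2)
    return out
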