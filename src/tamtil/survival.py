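"""Prognostic stratification: cohort filters, median splits, KM, log-rank, Cox.

The combined TAM/TIL analysis splits each infiltration measure at its
cohort median, crosses the two binary levels into four groups
(low TAM/high TIL, low TAM/low TIL, high TAM/high TIL, high TAM/low TIL)
and compares their survival by Kaplan-Meier estimates, log-rank tests and
Cox proportional-hazards models with the low TAM/high TIL group as
reference.  Kaplan-Meier, log-rank and Cox fitting are delegated to
``lifelines``; the auxiliary group-comparison tests to ``scipy``.

Cohort filters mirror survival-study practice: restrict to newly
diagnosed, macroscopically completely resected tumors (Simpson I-III /
GTR) and require a minimum follow-up for *event-free* records only --
patients whose event occurred before the threshold carry information and
are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "GROUP_LABELS",
    "KMEstimate",
    "filter_survival_cohort",
    "median_split",
    "combine_tam_til_groups",
    "kaplan_meier",
    "logrank_test",
    "cox_ph",
    "z_transform",
    "chi_square_test",
    "two_group_compare",
]

#: Four-group labels from crossing median-split TAM and TIL levels, in the
#: conventional order (reference group first).
GROUP_LABELS = (
    "lowTAM_highTIL",
    "lowTAM_lowTIL",
    "highTAM_highTIL",
    "highTAM_lowTIL",
)


def filter_survival_cohort(
    clinical: pd.DataFrame,
    min_followup_months: float = 60.0,
    require_gtr: bool = True,
    newly_diagnosed_only: bool = True,
) -> pd.DataFrame:
    """Apply survival-cohort inclusion criteria.

    Keeps records that (i) are newly diagnosed (if requested), (ii) had a
    gross total resection -- Simpson grade I-III via a ``simpson`` column
    or a boolean ``gtr`` column -- and (iii) either experienced the event
    or were followed for at least ``min_followup_months``.  Dropping
    short-follow-up censored records avoids immortal-time distortion while
    early events remain informative.
    """
    keep = pd.Series(True, index=clinical.index)
    if newly_diagnosed_only and "status" in clinical.columns:
        keep &= clinical["status"].eq("newly_diagnosed")
    if require_gtr:
        if "simpson" in clinical.columns:
            keep &= clinical["simpson"].le(3)
        elif "gtr" in clinical.columns:
            keep &= clinical["gtr"].astype(bool)
        else:
            raise ValueError("require_gtr: clinical table has neither 'simpson' nor 'gtr'")
    event = clinical["event"].astype(int)
    keep &= event.eq(1) | clinical["followup_months"].ge(min_followup_months)
    out = clinical[keep]
    if len(out) == 0:
        warnings.warn("survival filters removed every record", stacklevel=2)
    return out


def median_split(values: pd.Series) -> tuple[pd.Series, float]:
    """Dichotomise at the cohort median; ties at the median go to 'low'.

    Returns (levels, threshold) where a level is ``'high'`` iff the value
    is strictly greater than the median.
    """
    v = pd.to_numeric(values, errors="raise")
    if len(v) < 2:
        raise ValueError("median split needs at least 2 values")
    if np.ptp(v.to_numpy(dtype=float)) == 0:
        raise ValueError("all values identical; median split is degenerate")
    thr = float(v.median())
    levels = pd.Series(np.where(v > thr, "high", "low"), index=v.index, name=values.name)
    return levels, thr


def combine_tam_til_groups(tam_levels: pd.Series, til_levels: pd.Series) -> pd.Series:
    """Cross TAM and TIL low/high levels into the four combined groups."""
    if set(tam_levels.index) != set(til_levels.index):
        raise ValueError("TAM and TIL level series cover different samples")
    til_levels = til_levels.loc[tam_levels.index]
    combined = tam_levels.str.cat(til_levels, sep="|").map(
        {
            "low|high": "lowTAM_highTIL",
            "low|low": "lowTAM_lowTIL",
            "high|high": "highTAM_highTIL",
            "high|low": "highTAM_lowTIL",
        }
    )
    if combined.isna().any():
        raise ValueError("levels must be 'low' or 'high'")
    return combined.rename("tam_til_group")


@dataclass
class KMEstimate:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray        # event/censor times in ascending order
    survival: np.ndarray     # S(t) at those times
    median: float            # first time with S <= 0.5 (inf if never reached)
    n: int
    n_events: int


def kaplan_meier(records: pd.DataFrame, groups: pd.Series | None = None) -> dict[str, KMEstimate]:
    """Kaplan-Meier estimates per group (events precede censorings at ties).

    ``records`` needs ``followup_months`` and ``event`` columns; ``groups``
    assigns each sample a group label (one pooled group when omitted).
    """
    if groups is None:
        groups = pd.Series("all", index=records.index)
    groups = groups.loc[records.index]
    out: dict[str, KMEstimate] = {}
    for g in pd.unique(groups):
        sub = records[groups == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["followup_months"], sub["event"])
        sf = kmf.survival_function_.iloc[:, 0]
        out[str(g)] = KMEstimate(
            group=str(g),
            times=sf.index.to_numpy(dtype=float),
            survival=sf.to_numpy(dtype=float),
            median=float(kmf.median_survival_time_),
            n=len(sub),
            n_events=int(sub["event"].sum()),
        )
    return out


def logrank_test(records: pd.DataFrame, groups: pd.Series) -> tuple[float, int, float]:
    """K-group log-rank test; returns (chi-square, df, p)."""
    groups = groups.loc[records.index]
    k = groups.nunique()
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if records["event"].sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(
        records["followup_months"], groups, records["event"]
    )
    return float(res.test_statistic), k - 1, float(res.p_value)


def cox_ph(
    records: pd.DataFrame,
    covariates: pd.DataFrame,
    ties_method: str = "efron",
) -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per covariate.

    ``covariates`` must be numeric (encode categorical covariates as
    dummies first; for the combined four-group analysis use
    ``lowTAM_highTIL`` as the omitted reference).  Returns a DataFrame
    with ``coef``, ``hr``, ``ci_lower``, ``ci_upper``, ``p`` and carries
    ``n``/``n_events`` in ``attrs``.  Ties are handled by the Efron
    approximation by default ('breslow' available).
    """
    if ties_method not in ("efron", "breslow"):
        raise ValueError("ties_method must be 'efron' or 'breslow'")
    cov = covariates.loc[records.index].astype(float)
    if (cov.nunique() <= 1).any():
        bad = cov.columns[cov.nunique() <= 1][0]
        raise ValueError(f"covariate {bad!r} is constant")
    if np.linalg.matrix_rank(cov.to_numpy()) < cov.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    if records["event"].sum() < 1:
        raise ValueError("Cox model needs at least one event")
    df = cov.copy()
    df["followup_months"] = records["followup_months"].astype(float)
    df["event"] = records["event"].astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitter = CoxPHFitter()
        fitter.fit(
            df,
            duration_col="followup_months",
            event_col="event",
            fit_options={"step_size": 0.95},
        )
    summ = fitter.summary
    out = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "ci_lower": summ["exp(coef) lower 95%"],
            "ci_upper": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    out.attrs["n"] = len(df)
    out.attrs["n_events"] = int(df["event"].sum())
    out.attrs["ties_method"] = ties_method
    return out


def z_transform(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Standardise to mean 0, sample SD 1 (ddof = 1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-transform needs at least 2 values")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("z-transform undefined for zero-variance input")
    z = (x - x.mean()) / s
    if isinstance(values, pd.Series):
        return pd.Series(z, index=values.index, name=values.name)
    return z


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(dof), float(p)


def two_group_compare(
    values: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray | None = None,
    paired_with: pd.Series | np.ndarray | None = None,
    exact_threshold: int = 20,
) -> tuple[str, float, float]:
    """Nonparametric two-group comparison; returns (test name, statistic, p).

    Unpaired (``labels`` given): Mann-Whitney U, exact for combined
    n <= ``exact_threshold`` without ties, otherwise the tie-corrected
    normal approximation.  Paired (``paired_with`` given): Wilcoxon
    matched-pairs signed-rank test; identical vectors are degenerate.
    """
    x = np.asarray(values, dtype=float)
    if paired_with is not None:
        y = np.asarray(paired_with, dtype=float)
        if len(x) != len(y):
            raise ValueError("paired vectors must have equal length")
        if np.all(x == y):
            raise ValueError("all paired differences are zero; signed-rank test degenerate")
        stat, p = stats.wilcoxon(x, y)
        return "wilcoxon_signed_rank", float(stat), float(p)
    if labels is None:
        raise ValueError("provide either labels (unpaired) or paired_with (paired)")
    lab = np.asarray(labels)
    uniq = pd.unique(lab)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {len(uniq)}")
    a, b = x[lab == uniq[0]], x[lab == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    has_ties = len(np.unique(x)) < len(x)
    method = "exact" if (len(x) <= exact_threshold and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return f"mann_whitney_u_{method}", float(res.statistic), float(res.pvalue)
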