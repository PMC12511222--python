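"""Reading, validation and preprocessing of methylation beta matrices and clinical tables.

A *beta matrix* is a ``pandas.DataFrame`` of methylation beta values in
[0, 1], with CpG probe identifiers on the row index and sample identifiers
on the columns (the common array convention).  A *clinical table* is a
``DataFrame`` indexed by sample id carrying measured immune infiltration
(as percent of total cell count, %TCC), WHO grade, demographics, resection
information and right-censored survival fields.

The two preprocessing steps every downstream stage relies on are
:func:`merge_by_common_cpgs` (cross-platform merge by probe-id
intersection) and :func:`drop_incomplete_cpgs` (removal of probes with a
missing value in any sample).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrixError",
    "ClinicalTableError",
    "read_beta_matrix",
    "write_beta_matrix",
    "validate_beta_matrix",
    "merge_by_common_cpgs",
    "drop_incomplete_cpgs",
    "read_clinical_table",
    "write_clinical_table",
    "validate_clinical_table",
]

#: Missing-value tokens recognised by default when parsing beta matrices.
DEFAULT_NA_TOKENS = ("NA", "NaN", "nan", "")

#: Values within this distance outside [0, 1] are clamped; beyond it the
#: file is rejected (guards against M-value / logit matrices loaded by
#: mistake).
BETA_TOLERANCE = 1e-9

_GRADES = (1, 2, 3)


class BetaMatrixError(ValueError):
    """Raised when a beta matrix violates its structural contract."""


class ClinicalTableError(ValueError):
    """Raised when a clinical table violates its structural contract."""


def _sep_for(path: str, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
        return "\t" if dialect == "tsv" else ","
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def validate_beta_matrix(m: pd.DataFrame, where: str = "beta matrix") -> pd.DataFrame:
    """Validate ids and value range of a beta matrix; return a clamped copy.

    Duplicate CpG or sample ids are rejected.  Non-missing values must lie
    in ``[-BETA_TOLERANCE, 1 + BETA_TOLERANCE]``; values in the tolerance
    band are clamped onto [0, 1].
    """
    if m.index.has_duplicates:
        dup = m.index[m.index.duplicated()][0]
        raise BetaMatrixError(f"{where}: duplicate CpG id {dup!r}")
    if m.columns.has_duplicates:
        dup = m.columns[m.columns.duplicated()][0]
        raise BetaMatrixError(f"{where}: duplicate sample id {dup!r}")
    values = m.to_numpy(dtype=float, copy=True)
    with np.errstate(invalid="ignore"):
        bad = (values < -BETA_TOLERANCE) | (values > 1.0 + BETA_TOLERANCE)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise BetaMatrixError(
            f"{where}: value {values[i, j]!r} outside [0, 1] at "
            f"CpG {m.index[i]!r}, sample {m.columns[j]!r}"
        )
    np.clip(values, 0.0, 1.0, out=values)
    return pd.DataFrame(values, index=m.index.astype(str), columns=m.columns.astype(str))


def read_beta_matrix(
    path,
    dialect: str | None = None,
    na_tokens: tuple[str, ...] = DEFAULT_NA_TOKENS,
) -> pd.DataFrame:
    """Read a delimited beta matrix (first column CpG id, header sample ids).

    The field separator is taken from ``dialect`` ('tsv'/'csv') or inferred
    from the file extension.  Cells equal to one of ``na_tokens`` become
    missing values and survive until :func:`drop_incomplete_cpgs`.
    Non-numeric cells and out-of-range values raise :class:`BetaMatrixError`
    naming the offending CpG and sample.
    """
    sep = _sep_for(path, dialect)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw = raw.apply(lambda col: col.str.strip())
    is_na = raw.isin(na_tokens)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    unparsed = numeric.isna() & ~is_na
    if unparsed.to_numpy().any():
        i, j = np.argwhere(unparsed.to_numpy())[0]
        raise BetaMatrixError(
            f"{path}: non-numeric cell {raw.iat[i, j]!r} at "
            f"CpG {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    return validate_beta_matrix(numeric, where=str(path))


def write_beta_matrix(m: pd.DataFrame, path, dialect: str | None = None, na_token: str = "NA") -> None:
    """Write a beta matrix as delimited text (full float precision)."""
    sep = _sep_for(path, dialect)
    m.to_csv(path, sep=sep, na_rep=na_token, index_label="cpg_id")


def merge_by_common_cpgs(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Merge two beta matrices by probe-id intersection.

    The typical use is combining cohorts profiled on different array
    platforms (450K vs EPIC) that share only part of their probe sets.
    Rows are the CpG intersection in ``a``'s order; columns are the union
    of samples, which must be disjoint between inputs.
    """
    overlap = a.columns.intersection(b.columns)
    if len(overlap):
        raise BetaMatrixError(f"sample ids present in both matrices: {list(overlap[:5])}")
    common = a.index[a.index.isin(b.index)]
    if len(common) == 0:
        raise BetaMatrixError("merge: no CpG identifiers in common")
    return pd.concat([a.loc[common], b.loc[common]], axis=1)


def drop_incomplete_cpgs(m: pd.DataFrame) -> pd.DataFrame:
    """Remove every CpG with a missing value in any sample.

    Idempotent; the sample set is unchanged.  Raises
    :class:`BetaMatrixError` if no complete CpG remains.
    """
    out = m.dropna(axis=0, how="any")
    if out.shape[0] == 0:
        raise BetaMatrixError("drop_incomplete_cpgs: no complete CpG rows remain")
    return out


# ---------------------------------------------------------------------------
# clinical tables

REQUIRED_CLINICAL_COLUMNS = ("sample_id",)

_CATEGORICALS = {
    "sex": ("female", "male"),
    "status": ("newly_diagnosed", "recurrent"),
}


def validate_clinical_table(t: pd.DataFrame) -> pd.DataFrame:
    """Type-check and normalise a clinical table (indexed by sample id).

    Checks applied to columns that are present: ``who_grade`` in {1,2,3},
    ``followup_months`` >= 0, ``event`` in {0,1}, infiltration percentages
    non-negative, ``simpson`` in 1..5; ``sex``/``status`` labels are
    lower-cased and validated.  Unknown columns pass through untouched.
    """
    t = t.copy()
    if t.index.has_duplicates:
        dup = t.index[t.index.duplicated()][0]
        raise ClinicalTableError(f"duplicate sample id {dup!r}")
    if "who_grade" in t:
        t["who_grade"] = pd.to_numeric(t["who_grade"], errors="raise").astype(int)
        bad = ~t["who_grade"].isin(_GRADES)
        if bad.any():
            raise ClinicalTableError(
                f"who_grade outside {{1,2,3}} for sample {t.index[bad][0]!r}"
            )
    for col in ("tam_pct", "til_pct", "m2_pct", "followup_months", "age_years"):
        if col in t:
            t[col] = pd.to_numeric(t[col], errors="raise").astype(float)
            neg = t[col] < 0
            if neg.any():
                raise ClinicalTableError(
                    f"negative {col} for sample {t.index[neg][0]!r}"
                )
    if "event" in t:
        t["event"] = pd.to_numeric(t["event"], errors="raise").astype(int)
        if not t["event"].isin((0, 1)).all():
            raise ClinicalTableError("event must be 0 or 1")
    if "simpson" in t:
        t["simpson"] = pd.to_numeric(t["simpson"], errors="raise").astype(int)
        if not t["simpson"].isin(range(1, 6)).all():
            raise ClinicalTableError("simpson grade must be in 1..5")
    for col, levels in _CATEGORICALS.items():
        if col in t:
            t[col] = t[col].astype(str).str.strip().str.lower()
            bad = ~t[col].isin(levels)
            if bad.any():
                raise ClinicalTableError(
                    f"unknown {col} label {t[col][bad].iloc[0]!r}; expected one of {levels}"
                )
    return t


def read_clinical_table(path) -> pd.DataFrame:
    """Read and validate a clinical CSV with a ``sample_id`` column."""
    t = pd.read_csv(path)
    for col in REQUIRED_CLINICAL_COLUMNS:
        if col not in t.columns:
            raise ClinicalTableError(f"{path}: missing mandatory column {col!r}")
    t = t.set_index("sample_id")
    t.index = t.index.astype(str)
    return validate_clinical_table(t)


def write_clinical_table(t: pd.DataFrame, path) -> None:
    t.to_csv(path, index_label="sample_id")
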