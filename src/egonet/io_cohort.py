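"""Cohort data model, CSV readers/writers and preprocessing.

A cohort table has one row per subject: 15 Beck Suicide Intent Scale (SIS)
items scored 0-2, 14 emergency-room confounders, and a C-SSRS actual
lethality grade 1-6.  Preprocessing comprises SIS calibration (0-2 -> 1-3),
decimal-year date encoding, dichotomisation of the C-SSRS grade into a
binary lethality label (grade >= 4 is lethal), and k-nearest-neighbour
imputation of missing cells.

Calendar dates are converted to decimal years on read, so the in-memory
table is fully numeric; empty CSV cells denote missing values.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SIS_COLUMNS",
    "CONFOUNDER_COLUMNS",
    "DATE_COLUMNS",
    "CONTINUOUS_COLUMNS",
    "CSSRS_COLUMN",
    "ID_COLUMN",
    "DATA_COLUMNS",
    "CohortFormatError",
    "CohortValidationError",
    "ImputationError",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "calibrate_sis",
    "encode_date",
    "label_lethality",
    "impute_knn",
    "preprocess",
]

ID_COLUMN = "subject_id"
SIS_COLUMNS = [f"sis_{i}" for i in range(1, 16)]
CONFOUNDER_COLUMNS = [
    "sex",
    "age",
    "marital_status",
    "religion",
    "monthly_income",
    "living_status",
    "education",
    "urbanicity",
    "er_visit_date",
    "weekend_visit",
    "er_visit_time",
    "admission_route",
    "admission_transport",
    "discharge_date",
]
CSSRS_COLUMN = "cssrs_lethality"
DATA_COLUMNS = SIS_COLUMNS + CONFOUNDER_COLUMNS + [CSSRS_COLUMN]

#: date-valued confounders, stored as decimal years
DATE_COLUMNS = ("er_visit_date", "discharge_date")
#: columns imputed with the neighbour mean; everything else takes the mode
CONTINUOUS_COLUMNS = ("age", "monthly_income", "er_visit_date", "discharge_date")


class CohortFormatError(ValueError):
    """Malformed cohort file (missing or unexpected columns)."""


class CohortValidationError(ValueError):
    """A cell value outside its legal domain."""


class ImputationError(ValueError):
    """Imputation cannot proceed (e.g. a column entirely missing)."""


def calibrate_sis(raw):
    """Shift raw SIS scores from {0,1,2} to the calibrated {1,2,3} scale.

    Accepts a scalar or an array; missing values (NaN) pass through.
    """
    arr = np.asarray(raw, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
        bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
        raise CohortValidationError(f"raw SIS score {bad!r} outside {{0,1,2}}")
    out = arr + 1.0
    if np.isscalar(raw) or np.ndim(raw) == 0:
        return float(out)
    return out


def encode_date(date) -> float:
    """Encode a calendar date as a decimal year, e.g. 2013-06-30 -> 2013.492.

    The convention is ``year + (day_of_year - 1) / 366``, reported to three
    decimals; it is strictly increasing over the days of any one year.
    Accepts a :class:`datetime.date` or an ISO ``YYYY-MM-DD`` string.
    """
    if isinstance(date, str):
        try:
            date = _dt.date.fromisoformat(date)
        except ValueError as exc:
            raise CohortValidationError(f"invalid date {date!r}") from exc
    if isinstance(date, _dt.datetime):
        date = date.date()
    if not isinstance(date, _dt.date):
        raise CohortValidationError(f"cannot interpret {date!r} as a date")
    doy = date.timetuple().tm_yday
    return round(date.year + (doy - 1) / 366.0, 3)


def label_lethality(cssrs_grade):
    """Dichotomise a C-SSRS grade: grades 4-6 are lethal, 1-3 nonlethal."""
    arr = np.asarray(cssrs_grade, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and not np.isin(finite, np.arange(1.0, 7.0)).all():
        bad = finite[~np.isin(finite, np.arange(1.0, 7.0))][0]
        raise CohortValidationError(f"C-SSRS grade {bad!r} outside {{1..6}}")
    out = (arr >= 4).astype(int)
    out = np.where(np.isfinite(arr), out, np.nan)
    if np.isscalar(cssrs_grade) or np.ndim(cssrs_grade) == 0:
        return int(out)
    return out


@dataclass
class CohortTable:
    """Per-subject cohort table with an explicit missingness mask.

    ``df`` holds one row per subject with columns ``subject_id``, the 15
    SIS items (raw 0-2 scale), the 14 confounders (dates as decimal years)
    and the C-SSRS grade; NaN marks missing cells.
    """

    df: pd.DataFrame
    imputation: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in [ID_COLUMN] + DATA_COLUMNS if c not in self.df.columns]
        if missing:
            raise CohortFormatError(f"missing column(s): {', '.join(missing)}")
        self.df = self.df[[ID_COLUMN] + DATA_COLUMNS].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        sis = self.df[SIS_COLUMNS].to_numpy(dtype=float)
        bad = np.isfinite(sis) & ~np.isin(sis, (0.0, 1.0, 2.0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise CohortValidationError(
                f"row {r}: SIS value {sis[r, c]!r} in {SIS_COLUMNS[c]} outside {{0,1,2}}"
            )
        grade = self.df[CSSRS_COLUMN].to_numpy(dtype=float)
        badg = np.isfinite(grade) & ~np.isin(grade, np.arange(1.0, 7.0))
        if badg.any():
            r = int(np.argwhere(badg)[0][0])
            raise CohortValidationError(f"row {r}: C-SSRS grade {grade[r]!r} outside {{1..6}}")
        age = self.df["age"].to_numpy(dtype=float)
        if (np.isfinite(age) & (age < 0)).any():
            r = int(np.argwhere(np.isfinite(age) & (age < 0))[0][0])
            raise CohortValidationError(f"row {r}: negative age")

    # -- basic views ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness indicator over the data columns."""
        return self.df[DATA_COLUMNS].isna()

    @property
    def sis_raw(self) -> np.ndarray:
        return self.df[SIS_COLUMNS].to_numpy(dtype=float)

    @property
    def sis_cal(self) -> np.ndarray:
        """Calibrated SIS scores on the 1-3 scale (NaN where missing)."""
        return calibrate_sis(self.sis_raw)

    @property
    def confounders(self) -> np.ndarray:
        return self.df[CONFOUNDER_COLUMNS].to_numpy(dtype=float)

    @property
    def cssrs(self) -> np.ndarray:
        return self.df[CSSRS_COLUMN].to_numpy(dtype=float)

    @property
    def lethal(self) -> np.ndarray:
        """Binary lethality label (NaN where the C-SSRS grade is missing)."""
        return label_lethality(self.cssrs)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), imputation=self.imputation)


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV.

    Empty cells denote missing values.  The two date confounders may be
    given either as ISO ``YYYY-MM-DD`` strings or as already-encoded
    decimal years; ISO dates are converted on read.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in [ID_COLUMN] + DATA_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s): {', '.join(missing)}")

    def _to_float(val: str, col: str, row: int) -> float:
        if val == "":
            return np.nan
        if col in DATE_COLUMNS and "-" in val.strip("-"):
            return encode_date(val)
        try:
            return float(val)
        except ValueError as exc:
            raise CohortValidationError(
                f"row {row}: cannot parse {val!r} in column {col}"
            ) from exc

    data = {ID_COLUMN: df[ID_COLUMN].astype(str)}
    for col in DATA_COLUMNS:
        data[col] = [
            _to_float(v, col, i) for i, v in enumerate(df[col].tolist())
        ]
    return CohortTable(pd.DataFrame(data))


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort CSV (empty string for missing cells)."""
    table.df.to_csv(path, index=False, na_rep="")


def _knn_impute_matrix(X: np.ndarray, k: int, continuous: np.ndarray):
    """Impute NaN cells of ``X`` in place; returns list of (row, col) filled.

    For each incomplete row, candidate donors are rows fully observed on
    the row's observed feature set plus the target column; distances are
    Euclidean on the standardised observed features.  Continuous columns
    receive the mean of the k nearest donors, coded/ordinal columns the
    mode (smallest value on ties).  Observed cells are never altered.
    """
    n, m = X.shape
    obs = np.isfinite(X)
    if not (~obs).any():
        return []
    if (~obs).all(axis=0).any():
        col = int(np.argwhere((~obs).all(axis=0))[0][0])
        raise ImputationError(f"column index {col} is entirely missing")

    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    filled: list[tuple[int, int]] = []
    out = X  # in-place by contract of the caller (operates on a copy)
    for r in np.flatnonzero(~obs.all(axis=1)):
        feat = np.flatnonzero(obs[r])
        targets = np.flatnonzero(~obs[r])
        donors_base = obs[:, feat].all(axis=1)
        donors_base[r] = False
        for c in targets:
            donors = np.flatnonzero(donors_base & obs[:, c])
            if donors.size < k:
                raise ImputationError(
                    f"row {r}, column index {c}: only {donors.size} donor rows "
                    f"complete on the shared features (need k={k})"
                )
            d2 = ((Z[donors][:, feat] - Z[r, feat]) ** 2).sum(axis=1)
            nearest = donors[np.argsort(d2, kind="stable")[:k]]
            vals = X[nearest, c]
            if continuous[c]:
                out[r, c] = vals.mean()
            else:
                uniq, counts = np.unique(vals, return_counts=True)
                out[r, c] = uniq[np.argmax(counts)]
            filled.append((int(r), int(c)))
    return filled


def impute_knn(table: CohortTable, k: int = 10) -> CohortTable:
    """k-nearest-neighbour imputation of every missing cell.

    Returns a new table whose mask is all-false; the original is not
    modified.  Provenance (k and the imputed cells) is recorded on the
    returned table's ``imputation`` attribute.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    X = table.df[DATA_COLUMNS].to_numpy(dtype=float).copy()
    continuous = np.array([c in CONTINUOUS_COLUMNS for c in DATA_COLUMNS])
    filled = _knn_impute_matrix(X, k, continuous)
    df = table.df.copy()
    df[DATA_COLUMNS] = X
    provenance = {
        "method": "knn",
        "k": k,
        "n_imputed": len(filled),
        "cells": [[r, DATA_COLUMNS[c]] for r, c in filled],
    }
    return CohortTable(df, imputation=provenance)


def preprocess(table: CohortTable, k: int = 10) -> CohortTable:
    """Full preprocessing chain: kNN imputation (raw scale) if needed.

    Calibration and lethality labels are exposed as views
    (:attr:`CohortTable.sis_cal`, :attr:`CohortTable.lethal`) and need no
    separate pass.  When the table has no missing cells the imputation
    step is skipped.
    """
    if table.mask.to_numpy().any():
        return impute_knn(table, k=k)
    out = table.copy()
    out.imputation = {"method": "none", "n_imputed": 0}
    return out
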