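"""Readers and writers for every tabular artifact in the pipeline.

All files are delimited text (comma, one-line header).  Synthetic
populations may additionally be written in Parquet for scale; both formats
round-trip losslessly.  Suppressed census cells are represented in memory
as missing values of a pandas nullable-integer column — parsing never
coerces the suppression sentinel to zero.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .categories import (
    AGE_MIN,
    AGE_MAX_EXCL,
    ETHNICITY_PRIORITY,
    NZDEP_QUINTILES,
    SEXES,
    SMOKING_LEVELS,
    UNKNOWN,
)
from .errors import ParseError, SchemaError, ValidationError

#: Default disclosure-control sentinel for suppressed census cells.
DEFAULT_SENTINEL = "..C"

#: Stratum (census cross-tab) columns: four conditioning variables plus one
#: count column per smoking category.
CENSUS_STRATUM_COLUMNS = ["age_band_low", "sex", "ethnicity", "nzdep_quintile"]
CENSUS_COUNT_COLUMNS = list(SMOKING_LEVELS)
CENSUS_COLUMNS = CENSUS_STRATUM_COLUMNS + CENSUS_COUNT_COLUMNS

#: Fixed column order of a synthetic population file.
POPULATION_COLUMNS = [
    "person_id",
    "age",
    "sex",
    "ethnicity",
    "nzdep_quintile",
    "smoking",
    "diabetes",
    "prior_cvd",
    "ll_med",
    "bpl_med",
    "sbp",
    "tc_hdl",
    "fam_hx",
]

_BOOL_COLUMNS = ["diabetes", "prior_cvd", "ll_med", "bpl_med", "fam_hx"]

#: Individual-level linked administrative records (disease + medication flags).
ADMIN_COLUMNS = [
    "person_id",
    "age",
    "sex",
    "ethnicity",
    "diabetes",
    "prior_cvd",
    "ll_med",
    "bpl_med",
]

#: Complete-case donor cohort records (population columns, all observed).
COHORT_COLUMNS = POPULATION_COLUMNS

REFERENCE_COLUMNS = ["stratum", "estimate", "ci_low", "ci_high", "n"]

_VALID_ETH = set(ETHNICITY_PRIORITY) | {UNKNOWN}
_VALID_NZDEP = {str(q) for q in NZDEP_QUINTILES} | {UNKNOWN}


# ---------------------------------------------------------------------------
# census cross-tab
# ---------------------------------------------------------------------------

def read_census_crosstab(
    path: str | os.PathLike,
    sentinel: str = DEFAULT_SENTINEL,
    enforce_dialect: bool = True,
) -> pd.DataFrame:
    """Read an aggregated census cross-tabulation with cell suppression.

    Returns a frame with one row per stratum (age band lower bound x sex x
    ethnicity x deprivation quintile) and three nullable-Int64 smoking-count
    columns in which ``pd.NA`` marks a suppressed cell.  Row order is
    preserved.

    Parameters
    ----------
    sentinel:
        The suppression code used by the file dialect (default ``"..C"``).
    enforce_dialect:
        When true, reject non-sentinel counts in 1..5 — under the
        disclosure-control rule any cell below 6 (other than an exact zero)
        must have been suppressed, so such a value indicates a corrupt file.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CENSUS_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"census file {path} is missing columns {missing}")
    raw = raw[CENSUS_COLUMNS].copy()

    out = pd.DataFrame(index=raw.index)
    try:
        out["age_band_low"] = raw["age_band_low"].astype(int)
    except ValueError as exc:
        raise ParseError(f"non-integer age_band_low in {path}: {exc}") from None
    bad_age = ~out["age_band_low"].between(AGE_MIN, AGE_MAX_EXCL - 1)
    if bad_age.any():
        raise SchemaError(
            f"age_band_low outside [{AGE_MIN}, {AGE_MAX_EXCL - 1}] "
            f"at row(s) {list(out.index[bad_age][:5])}"
        )
    for col, valid in (
        ("sex", set(SEXES)),
        ("ethnicity", _VALID_ETH),
        ("nzdep_quintile", _VALID_NZDEP),
    ):
        bad = ~raw[col].isin(valid)
        if bad.any():
            labels = sorted(raw.loc[bad, col].unique())
            raise SchemaError(f"unknown {col} label(s) {labels} in {path}")
        out[col] = raw[col]

    for col in CENSUS_COUNT_COLUMNS:
        cells = raw[col].str.strip()
        is_sent = cells == sentinel
        numeric = pd.to_numeric(cells.where(~is_sent), errors="coerce")
        bad = numeric.isna() & ~is_sent
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"malformed count {cells[row]!r} in column {col!r}, "
                f"data row {row} of {path}"
            )
        frac = numeric.dropna() % 1
        if (frac != 0).any() or (numeric.dropna() < 0).any():
            row = int(numeric.index[(numeric % 1 != 0) | (numeric < 0)][0])
            raise ParseError(
                f"non-integer or negative count in column {col!r}, "
                f"data row {row} of {path}"
            )
        parsed = numeric.astype("Int64")
        if enforce_dialect:
            small = parsed.notna() & (parsed >= 1) & (parsed <= 5)
            if small.any():
                row = int(small.idxmax())
                raise SchemaError(
                    f"unsuppressed small count {int(parsed[row])} in column "
                    f"{col!r}, data row {row} of {path}: the dialect "
                    "suppresses counts 1-5"
                )
        out[col] = parsed
    return out


def write_census_crosstab(
    strata: pd.DataFrame,
    path: str | os.PathLike,
    sentinel: str = DEFAULT_SENTINEL,
) -> None:
    """Write a census cross-tab, rendering suppressed cells as the sentinel."""
    out = strata[CENSUS_COLUMNS].copy()
    for col in CENSUS_COUNT_COLUMNS:
        vals = out[col]
        out[col] = vals.astype(object).where(vals.notna(), sentinel)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def validate_population(pop: pd.DataFrame, allow_incomplete: bool = False) -> None:
    """Check person-level invariants, naming the first offending person_id.

    ``allow_incomplete`` permits missing sbp / tc_hdl / fam_hx (the state of
    a population before imputation); all other fields must always be valid.
    """
    missing = [c for c in POPULATION_COLUMNS if c not in pop.columns]
    if missing:
        raise SchemaError(f"population is missing columns {missing}")

    def _offender(mask: pd.Series, what: str) -> None:
        if mask.any():
            pid = pop.loc[mask, "person_id"].iloc[0]
            raise ValidationError(f"person {pid!r}: {what}")

    age = pop["age"].astype(float)
    _offender(~((age >= AGE_MIN) & (age < AGE_MAX_EXCL)) | age.isna(),
              f"age outside [{AGE_MIN}, {AGE_MAX_EXCL})")
    _offender(~pop["sex"].isin(SEXES), "invalid sex")
    _offender(~pop["ethnicity"].isin(ETHNICITY_PRIORITY),
              "ethnicity not one of the seven resolved categories")
    _offender(~pop["nzdep_quintile"].astype(int).isin(NZDEP_QUINTILES),
              "nzdep_quintile outside 1..5")
    _offender(~pop["smoking"].isin(SMOKING_LEVELS), "invalid smoking category")
    for col in ("sbp", "tc_hdl"):
        vals = pop[col].astype(float)
        bad = ~(np.isfinite(vals) & (vals > 0))
        if allow_incomplete:
            bad &= vals.notna()
        _offender(bad, f"{col} not finite and positive")
    if not allow_incomplete:
        _offender(pop["fam_hx"].isna(), "fam_hx missing")


def write_population(
    pop: pd.DataFrame,
    path: str | os.PathLike,
    allow_incomplete: bool = False,
) -> None:
    """Write a population (CSV or, if the path ends in .parquet, Parquet).

    Refuses to write a population violating person invariants; booleans are
    serialized as 0/1 so the CSV round-trips exactly.
    """
    validate_population(pop, allow_incomplete=allow_incomplete)
    out = pop[POPULATION_COLUMNS].copy()
    if str(path).endswith(".parquet"):
        out.to_parquet(path, index=False)
        return
    for col in _BOOL_COLUMNS:
        vals = out[col]
        # keep NA (pre-imputation fam_hx) distinguishable from False
        out[col] = vals.map(lambda v: "" if pd.isna(v) else int(bool(v)))
    out.to_csv(path, index=False, float_format="%.17g")


def read_population(path: str | os.PathLike) -> pd.DataFrame:
    """Read a population written by :func:`write_population`."""
    if str(path).endswith(".parquet"):
        pop = pd.read_parquet(path)
    else:
        pop = pd.read_csv(path, dtype={"person_id": str})
        for col in _BOOL_COLUMNS:
            vals = pop[col]
            pop[col] = vals.map(lambda v: pd.NA if pd.isna(v) else bool(v)).astype(
                object if vals.isna().any() else bool
            )
    missing = [c for c in POPULATION_COLUMNS if c not in pop.columns]
    if missing:
        raise SchemaError(f"population file {path} is missing columns {missing}")
    pop["nzdep_quintile"] = pop["nzdep_quintile"].astype(int)
    return pop[POPULATION_COLUMNS]


# ---------------------------------------------------------------------------
# administrative records and donor cohort
# ---------------------------------------------------------------------------

def read_admin_records(path: str | os.PathLike) -> pd.DataFrame:
    """Read linked administrative records (disease and medication flags)."""
    df = pd.read_csv(path, dtype={"person_id": str})
    missing = [c for c in ADMIN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"admin file {path} is missing columns {missing}")
    for col in ("diabetes", "prior_cvd", "ll_med", "bpl_med"):
        df[col] = df[col].astype(int).astype(bool)
    return df[ADMIN_COLUMNS]


def write_admin_records(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df[ADMIN_COLUMNS].copy()
    for col in ("diabetes", "prior_cvd", "ll_med", "bpl_med"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_cohort(path: str | os.PathLike) -> pd.DataFrame:
    """Read the complete-case donor cohort; every field must be observed."""
    df = read_population(path)
    if df[POPULATION_COLUMNS].isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValidationError(f"cohort {path} has missing values in {bad}")
    validate_population(df)
    return df


def write_cohort(df: pd.DataFrame, path: str | os.PathLike) -> None:
    write_population(df, path)


# ---------------------------------------------------------------------------
# external reference tables
# ---------------------------------------------------------------------------

def read_reference_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read external stratum-level estimates with 95% confidence intervals.

    Enforces ci_low <= estimate <= ci_high per row; the optional ``n``
    column carries the source sample size.
    """
    df = pd.read_csv(path)
    required = ["stratum", "estimate", "ci_low", "ci_high"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"reference table {path} is missing columns {missing}")
    if "n" not in df.columns:
        df["n"] = pd.NA
    bad = ~((df["ci_low"] <= df["estimate"]) & (df["estimate"] <= df["ci_high"]))
    if bad.any():
        strata = df.loc[bad, "stratum"].tolist()
        raise ValidationError(
            f"reference table {path}: estimate outside its CI for strata {strata}"
        )
    return df[REFERENCE_COLUMNS]


def write_reference_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in REFERENCE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)
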