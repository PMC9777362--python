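"""Reading and writing respondent-level CSV files.

The canonical respondent schema is one UTF-8, comma-delimited row per
respondent with header::

    respondent_id,wave,age_group,gender,stratum,cluster,weight,
    feeling_low,irritability,nervousness,sleep_difficulty,ls

Missing item or ladder responses are encoded as empty fields.  Structural
fields (demographics, design columns) must parse; invalid item codes and
ladder values are loaded as missing with a logged count, mirroring how such
responses are treated as item non-response rather than record failure.
"""

from __future__ import annotations

import logging
from typing import Union

import numpy as np
import pandas as pd

from .errors import SchemaError
from .scoring import ITEM_COLUMNS

logger = logging.getLogger(__name__)

RESPONDENT_COLUMNS = (
    "respondent_id",
    "wave",
    "age_group",
    "gender",
    "stratum",
    "cluster",
    "weight",
    *ITEM_COLUMNS,
    "ls",
)

VALID_GENDERS = ("boy", "girl")
VALID_AGE_GROUPS = (11, 13, 15)


def write_respondents(df: pd.DataFrame, path) -> None:
    """Write a respondent table in the canonical schema (missing -> empty)."""
    out = df.loc[:, list(RESPONDENT_COLUMNS)].copy()
    for col in (*ITEM_COLUMNS, "ls"):
        out[col] = pd.array(
            np.rint(pd.to_numeric(out[col], errors="coerce")), dtype="Int64"
        )
    out.to_csv(path, index=False)


def read_respondents(path) -> pd.DataFrame:
    """Read and validate a respondent CSV.

    Returns a typed DataFrame in file order: ``age_group`` int, ``weight``
    float, items and ``ls`` float (NaN for missing or out-of-range values,
    whose counts are logged).  Raises :class:`SchemaError` for a missing
    column or an unparseable structural field, naming the offender and the
    data line number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in RESPONDENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")
    df = df.loc[:, list(RESPONDENT_COLUMNS)]
    if df.empty:
        return _finalize(df)

    def _bad_line(mask) -> int:
        return int(np.flatnonzero(mask)[0]) + 2  # header is line 1

    age = pd.to_numeric(df["age_group"], errors="coerce")
    bad = ~age.isin(VALID_AGE_GROUPS)
    if bad.any():
        raise SchemaError(
            f"line {_bad_line(bad)}: age_group must be one of {VALID_AGE_GROUPS}, "
            f"got {df.loc[bad, 'age_group'].iloc[0]!r}"
        )
    bad = ~df["gender"].isin(VALID_GENDERS)
    if bad.any():
        raise SchemaError(
            f"line {_bad_line(bad)}: gender must be one of {VALID_GENDERS}, "
            f"got {df.loc[bad, 'gender'].iloc[0]!r}"
        )
    def _float_or_nan(text: str) -> float:
        try:
            return float(text)
        except ValueError:
            return np.nan

    # str.__float__ is correctly rounded; pandas' fast parser can be 1 ulp off
    weight = df["weight"].map(_float_or_nan)
    bad = ~np.isfinite(weight) | (weight <= 0)
    if bad.any():
        raise SchemaError(
            f"line {_bad_line(bad)}: weight must be a positive number, "
            f"got {df.loc[bad, 'weight'].iloc[0]!r}"
        )
    for col in ("wave", "stratum", "cluster", "respondent_id"):
        bad = df[col].str.strip() == ""
        if bad.any():
            raise SchemaError(f"line {_bad_line(bad)}: empty {col}")

    out = df.copy()
    out["age_group"] = age.astype(int)
    out["weight"] = weight.astype(float)
    for col in ITEM_COLUMNS:
        raw = out[col].str.strip()
        vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        valid = vals.isin([1, 2, 3, 4, 5]) | vals.isna()
        n_bad = int((~valid).sum()) + int((vals.isna() & (raw != "")).sum())
        if n_bad:
            logger.warning("%s: %d invalid responses loaded as missing", col, n_bad)
        out[col] = vals.where(valid).astype(float)
    raw = out["ls"].str.strip()
    ls = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
    valid = (ls.isin(range(11))) | ls.isna()
    n_bad = int((~valid).sum()) + int((ls.isna() & (raw != "")).sum())
    if n_bad:
        logger.warning("ls: %d invalid ladder values loaded as missing", n_bad)
    out["ls"] = ls.where(valid).astype(float)
    return _finalize(out)


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        df = df.copy()
        for col in ("age_group",):
            df[col] = df[col].astype(int) if len(df) else pd.Series(dtype=int)
        for col in ("weight", *ITEM_COLUMNS, "ls"):
            df[col] = pd.Series(dtype=float)
    return df.reset_index(drop=True)
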