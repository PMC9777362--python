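"""Scoring of the HBSC-SCL psychological subscale and the Cantril ladder.

The four psychological symptom items (feeling low, irritability, nervousness,
sleep difficulty) are answered on a 5-level frequency scale coded
1 = "about every day" ... 5 = "rarely/never".  Analysis uses the reversed and
rescaled 0-4 codes (0 = "rarely/never" ... 4 = "about every day"); their sum is
the 0-16 psychological-health-complaints (PHC) score, higher meaning more
frequent and intense complaints.  The Cantril ladder (life satisfaction, LS)
is an integer from 0 (worst possible life) to 10 (best possible life).

The dichotomous gold-standard label used to calibrate a cutoff on the
continuous PHC scale is "at least 2 symptoms more than once a week", i.e. at
least two items with rescaled score >= 3 (original code <= 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from numbers import Real
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Fixed item order used in all I/O.
ITEM_COLUMNS = ("feeling_low", "irritability", "nervousness", "sleep_difficulty")

N_ITEMS = len(ITEM_COLUMNS)
PHC_MAX = 4 * N_ITEMS  # 16

#: Rescaled frequency at or above which a symptom counts as
#: "more than once a week" (includes "about every day").
GOLD_RESCALED_MIN = 3
#: Number of qualifying symptoms required for a gold-positive label.
GOLD_MIN_SYMPTOMS = 2


@dataclass(frozen=True)
class PhcScore:
    """A scored PHC value together with the number of items that produced it."""

    value: Optional[float]
    n_items_used: int


@dataclass(frozen=True)
class GoldLabel:
    """Dichotomous 'multiple frequent symptoms' label; missing if undecidable."""

    positive: Optional[bool]


def reverse_code(code: int) -> int:
    """Reverse a 1-5 frequency code (1 <-> 5, 2 <-> 4).  Involutive."""
    code = _check_code(code)
    return 6 - code


def rescale_item(code: int) -> int:
    """Map an original 1-5 item code to its reversed, rescaled 0-4 score.

    5 ("rarely/never") -> 0, 4 -> 1, 3 -> 2, 2 ("more than once a week") -> 3,
    1 ("about every day") -> 4.  Bijective on {1..5}.
    """
    return reverse_code(code) - 1


def _check_code(code) -> int:
    if not isinstance(code, Real) or isinstance(code, bool):
        raise ValidationError(f"item code must be an integer in 1..5, got {code!r}")
    if float(code) != int(code) or not 1 <= int(code) <= 5:
        raise ValidationError(f"item code must be an integer in 1..5, got {code!r}")
    return int(code)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return False


def phc_score(items: Sequence, min_items: int = N_ITEMS) -> PhcScore:
    """Sum the rescaled scores of the four symptom items into a 0-16 score.

    Parameters
    ----------
    items
        The four original item codes in the fixed item order; entries may be
        missing (``None``/NaN).
    min_items
        Minimum number of answered items required to emit a score.  With the
        default of 4 the score is a plain complete-case sum; with fewer, the
        partial sum is rescaled by ``4 / n_answered`` and rounded to the
        nearest integer (a prorated sum).
    """
    if len(items) != N_ITEMS:
        raise ValidationError(f"expected {N_ITEMS} items, got {len(items)}")
    if not 1 <= min_items <= N_ITEMS:
        raise ValidationError("min_items must be in 1..4")
    present = [v for v in items if not _is_missing(v)]
    n_used = len(present)
    if n_used < min_items:
        return PhcScore(value=None, n_items_used=n_used)
    partial = sum(rescale_item(v) for v in present)
    if n_used == N_ITEMS:
        return PhcScore(value=float(partial), n_items_used=n_used)
    return PhcScore(value=float(round(partial * N_ITEMS / n_used)), n_items_used=n_used)


def gold_standard(items: Sequence) -> GoldLabel:
    """Label a respondent gold-positive if >= 2 symptoms occur more than weekly.

    A symptom qualifies when its rescaled score is >= 3, i.e. the original
    code is 1 ("about every day") or 2 ("more than once a week").  The label
    is missing whenever any item is missing, since an unanswered item could
    change the count in either direction.
    """
    if len(items) != N_ITEMS:
        raise ValidationError(f"expected {N_ITEMS} items, got {len(items)}")
    if any(_is_missing(v) for v in items):
        return GoldLabel(positive=None)
    n_frequent = sum(rescale_item(v) >= GOLD_RESCALED_MIN for v in items)
    return GoldLabel(positive=n_frequent >= GOLD_MIN_SYMPTOMS)


def validate_ls(raw) -> Optional[int]:
    """Pass through an integer ladder score in 0..10; anything else is missing."""
    if _is_missing(raw):
        return None
    if isinstance(raw, str):
        raw = raw.strip()
        if raw == "":
            return None
        try:
            raw = float(raw)
        except ValueError:
            return None
    if isinstance(raw, bool) or not isinstance(raw, Real):
        return None
    value = float(raw)
    if not value.is_integer() or not 0 <= value <= 10:
        return None
    return int(value)


def score_frame(df: pd.DataFrame, min_items: int = N_ITEMS) -> pd.DataFrame:
    """Vectorised scoring of a respondent table.

    Returns a copy of ``df`` with four added columns:

    ``phc``
        the 0-16 PHC score (NaN when too few items answered),
    ``n_items``
        number of valid item responses used,
    ``gold``
        gold-standard label as 1.0/0.0 (NaN when any item missing),
    ``ls_valid``
        validated ladder score (NaN when absent or out of range).

    Item codes outside 1..5 and ladder values outside 0..10 are treated as
    missing; their counts are logged.
    """
    if not 1 <= min_items <= N_ITEMS:
        raise ValidationError("min_items must be in 1..4")
    out = df.copy()
    codes = np.full((len(df), N_ITEMS), np.nan)
    n_invalid_items = 0
    for j, col in enumerate(ITEM_COLUMNS):
        raw = pd.to_numeric(out[col], errors="coerce").to_numpy(dtype=float)
        valid = np.isfinite(raw) & (raw == np.round(raw)) & (raw >= 1) & (raw <= 5)
        n_invalid_items += int((~valid & np.isfinite(raw)).sum())
        codes[valid, j] = raw[valid]
    if n_invalid_items:
        logger.warning("%d item responses outside 1..5 treated as missing", n_invalid_items)

    answered = np.isfinite(codes)
    n_used = answered.sum(axis=1)
    rescaled = np.where(answered, 5.0 - codes, np.nan)
    partial = np.nansum(rescaled, axis=1)

    phc = np.full(len(df), np.nan)
    complete = n_used == N_ITEMS
    phc[complete] = partial[complete]
    if min_items < N_ITEMS:
        prorate = (n_used >= min_items) & ~complete
        phc[prorate] = np.round(partial[prorate] * N_ITEMS / n_used[prorate])

    frequent = np.where(answered, rescaled >= GOLD_RESCALED_MIN, False).sum(axis=1)
    gold = np.where(complete, (frequent >= GOLD_MIN_SYMPTOMS).astype(float), np.nan)

    ls_raw = pd.to_numeric(out["ls"], errors="coerce").to_numpy(dtype=float)
    ls_ok = np.isfinite(ls_raw) & (ls_raw == np.round(ls_raw)) & (ls_raw >= 0) & (ls_raw <= 10)
    n_bad_ls = int((~ls_ok & np.isfinite(ls_raw)).sum())
    if n_bad_ls:
        logger.warning("%d ladder values outside 0..10 treated as missing", n_bad_ls)
    ls_valid = np.where(ls_ok, ls_raw, np.nan)

    out["phc"] = phc
    out["n_items"] = n_used.astype(int)
    out["gold"] = gold
    out["ls_valid"] = ls_valid
    return out
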