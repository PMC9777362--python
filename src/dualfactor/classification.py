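"""Four-quadrant Dual Factor classification of (life satisfaction, PHC) pairs.

The Dual Factor Model treats subjective well-being and mental illness as
separate but related continua; crossing a life-satisfaction cutoff with a
symptom-load cutoff yields four mental states:

=============  ============  =============
state          well-being    symptom load
=============  ============  =============
Flourishing    high LS       low PHC
Struggling     high LS       high PHC
Languishing    low LS        low PHC
Floundering    low LS        high PHC
=============  ============  =============

Defaults follow the survey protocols: "high LS" is a ladder score at or
above 6, "high PHC" a symptom score at or above the ROC-calibrated cutoff
of 8.  Whether the cutoff value itself counts as "high" is a recorded,
configurable convention (inclusive on both axes by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from . import survey as _survey

logger = logging.getLogger(__name__)


class Quadrant(str, Enum):
    FLOURISHING = "Flourishing"
    STRUGGLING = "Struggling"
    LANGUISHING = "Languishing"
    FLOUNDERING = "Floundering"


QUADRANT_ORDER = (
    Quadrant.FLOURISHING,
    Quadrant.STRUGGLING,
    Quadrant.LANGUISHING,
    Quadrant.FLOUNDERING,
)


@dataclass(frozen=True)
class CutoffPair:
    """The two cutoffs and their boundary conventions."""

    ls_cutoff: float = 6.0
    phc_cutoff: float = 8.0
    ls_inclusive: bool = True  # high LS  <=>  ls  >= cutoff (else strict >)
    phc_inclusive: bool = True  # high PHC <=> phc >= cutoff (else strict >)

    def __post_init__(self):
        if not 0 <= self.ls_cutoff <= 10:
            raise ValidationError("ls_cutoff must be in [0, 10]")
        if not 0 <= self.phc_cutoff <= 16:
            raise ValidationError("phc_cutoff must be in [0, 16]")

    def high_ls(self, ls):
        ls = np.asarray(ls, dtype=float)
        return ls >= self.ls_cutoff if self.ls_inclusive else ls > self.ls_cutoff

    def high_phc(self, phc):
        phc = np.asarray(phc, dtype=float)
        return phc >= self.phc_cutoff if self.phc_inclusive else phc > self.phc_cutoff


DEFAULT_CUTOFFS = CutoffPair()


def classify(ls, phc, cutoffs: CutoffPair = DEFAULT_CUTOFFS) -> Optional[Quadrant]:
    """Assign one (ls, phc) pair to its quadrant; missing input gives None.

    Accepts real-valued inputs so group means can be placed in the same
    frame as individual respondents.
    """
    if ls is None or phc is None:
        return None
    ls, phc = float(ls), float(phc)
    if np.isnan(ls) or np.isnan(phc):
        return None
    high_ls = bool(cutoffs.high_ls(ls))
    high_phc = bool(cutoffs.high_phc(phc))
    if high_ls:
        return Quadrant.STRUGGLING if high_phc else Quadrant.FLOURISHING
    return Quadrant.FLOUNDERING if high_phc else Quadrant.LANGUISHING


def classify_frame(
    df: pd.DataFrame,
    cutoffs: CutoffPair = DEFAULT_CUTOFFS,
    ls_col: str = "ls_valid",
    phc_col: str = "phc",
) -> pd.DataFrame:
    """Add a ``quadrant`` column (NaN where either input is missing)."""
    out = df.copy()
    ls = pd.to_numeric(out[ls_col], errors="coerce").to_numpy(dtype=float)
    phc = pd.to_numeric(out[phc_col], errors="coerce").to_numpy(dtype=float)
    ok = np.isfinite(ls) & np.isfinite(phc)
    high_ls = cutoffs.high_ls(ls)
    high_phc = cutoffs.high_phc(phc)
    labels = np.where(
        high_ls,
        np.where(high_phc, Quadrant.STRUGGLING.value, Quadrant.FLOURISHING.value),
        np.where(high_phc, Quadrant.FLOUNDERING.value, Quadrant.LANGUISHING.value),
    ).astype(object)
    labels[~ok] = np.nan
    n_missing = int((~ok).sum())
    if n_missing:
        logger.info("classify_frame: %d records unclassifiable (missing ls/phc)", n_missing)
    out["quadrant"] = labels
    return out


def quadrant_distribution(
    df: pd.DataFrame,
    cutoffs: CutoffPair = DEFAULT_CUTOFFS,
    design: Optional[_survey.SurveyDesign] = None,
    groups: Sequence[str] = _survey.DEFAULT_GROUPS,
    ls_col: str = "ls_valid",
    phc_col: str = "phc",
) -> pd.DataFrame:
    """Weighted quadrant proportions per group cell, with design-based CIs.

    Proportions are means of 0/1 quadrant indicators over classified records,
    so the four proportions sum to one within each cell.  Cells with no
    classifiable records are reported with zero n and missing estimates.
    """
    classified = classify_frame(df, cutoffs, ls_col=ls_col, phc_col=phc_col)
    classified = classified[classified["quadrant"].notna()].copy()
    pieces = []
    for quadrant in QUADRANT_ORDER:
        classified["_indicator"] = (
            (classified["quadrant"] == quadrant.value).astype(float)
        )
        est = _survey.group_estimates(
            classified,
            "_indicator",
            design=design,
            groups=groups,
            statistic=f"prop_{quadrant.value}",
        )
        est.insert(len(groups), "quadrant", quadrant.value)
        pieces.append(est)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values([*groups, "quadrant"], kind="stable").reset_index(drop=True)
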