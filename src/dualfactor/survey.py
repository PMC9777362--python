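"""Design-based estimation for stratified, clustered, weighted surveys.

Point estimates are Hajek (ratio) weighted means.  Standard errors use
Taylor linearisation with the primary sampling units (school classes)
treated as sampled with replacement within strata and no finite-population
correction — the standard default when sampling fractions are unknown.

For a stratum *h* with :math:`n_h` PSUs and linearised PSU totals
:math:`z_{hj} = \\sum_{i \\in hj} w_i (y_i - \\hat{y}) / \\sum w`, the
variance contribution is :math:`n_h/(n_h-1) \\sum_j (z_{hj} - \\bar z_h)^2`.
Strata containing a single PSU contribute :math:`(z_{h1} - \\bar z)^2`
deviations from the grand PSU mean (``single_psu="centered"``); they can
instead be pooled into one pseudo-stratum (``single_psu="collapse"``).
Confidence intervals are normal-reference, estimate ± 1.96 · SE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, ValidationError

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

DEFAULT_GROUPS = ("wave", "gender", "age_group")


@dataclass(frozen=True)
class SurveyDesign:
    """Column names of the survey-design variables in a respondent table."""

    stratum: str = "stratum"
    cluster: str = "cluster"
    weight: str = "weight"
    single_psu: str = "centered"  # or "collapse"

    def __post_init__(self):
        if self.single_psu not in ("centered", "collapse"):
            raise ValidationError("single_psu must be 'centered' or 'collapse'")


def weighted_mean(values, weights=None) -> float:
    """Hajek weighted mean over non-missing pairs; NaN when nothing remains."""
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != values.shape:
            raise ValidationError("weights must match values in length")
    keep = np.isfinite(values) & np.isfinite(weights)
    if not keep.any():
        logger.warning("weighted_mean: all %d values missing", values.size)
        return float("nan")
    v, w = values[keep], weights[keep]
    return float(np.sum(w * v) / np.sum(w))


def linearized_se(
    values,
    strata,
    clusters,
    weights=None,
    single_psu: str = "centered",
) -> float:
    """Taylor-linearisation SE of the weighted mean under the survey design.

    With one stratum, one respondent per PSU and equal weights this reduces
    exactly to the classic SRS formula ``s / sqrt(n)`` with the
    ``1/(n-1)`` sample variance.
    """
    values = np.asarray(values, dtype=float)
    strata = np.asarray(strata)
    clusters = np.asarray(clusters)
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float)
    if not (len(values) == len(strata) == len(clusters) == len(weights)):
        raise ValidationError("values, strata, clusters, weights must align")
    keep = np.isfinite(values) & np.isfinite(weights)
    values, strata, clusters, weights = (
        values[keep],
        strata[keep],
        clusters[keep],
        weights[keep],
    )
    if values.size == 0:
        return float("nan")
    psu = pd.DataFrame(
        {
            "stratum": strata,
            "cluster": clusters,
            "z": weights * (values - np.sum(weights * values) / np.sum(weights))
            / np.sum(weights),
        }
    )
    totals = psu.groupby(["stratum", "cluster"], sort=True, observed=True)["z"].sum()
    if len(totals) < 2:
        raise DegenerateDesignError("need at least 2 clusters to estimate a variance")
    counts = totals.groupby(level="stratum", observed=True).size()
    singles = counts[counts == 1].index
    multi = counts[counts > 1].index

    if single_psu == "collapse" and len(singles) >= 2:
        collapsed = totals.loc[list(singles)]
        var_single = (
            len(collapsed)
            / (len(collapsed) - 1)
            * float(((collapsed - collapsed.mean()) ** 2).sum())
        )
    elif len(singles) > 0:
        # centered: deviations of lone PSU totals from the grand PSU mean
        grand = float(totals.mean())
        var_single = float(((totals.loc[list(singles)] - grand) ** 2).sum())
    else:
        var_single = 0.0

    var_multi = 0.0
    for h in multi:
        zh = totals.loc[h]
        nh = len(zh)
        var_multi += nh / (nh - 1) * float(((zh - zh.mean()) ** 2).sum())
    return float(np.sqrt(var_multi + var_single))


def design_se(df: pd.DataFrame, value_col: str, design: SurveyDesign) -> float:
    """Convenience wrapper for :func:`linearized_se` on a DataFrame."""
    return linearized_se(
        df[value_col],
        df[design.stratum],
        df[design.cluster],
        df[design.weight],
        single_psu=design.single_psu,
    )


def _srs_frame(df: pd.DataFrame) -> Tuple[pd.DataFrame, SurveyDesign]:
    """Equal-weight SRS pseudo-design: every respondent its own PSU."""
    out = df.copy()
    out["_stratum"] = "all"
    out["_cluster"] = np.arange(len(out))
    out["_weight"] = 1.0
    return out, SurveyDesign(stratum="_stratum", cluster="_cluster", weight="_weight")


def group_estimates(
    df: pd.DataFrame,
    value_col: str,
    design: Optional[SurveyDesign] = None,
    groups: Sequence[str] = DEFAULT_GROUPS,
    statistic: Optional[str] = None,
    z: float = Z_95,
) -> pd.DataFrame:
    """Design-based mean of ``value_col`` per cell of the group columns.

    One row per combination of observed group levels (the full cartesian
    product: combinations absent from the data are reported with zero n and
    missing estimates).  Returned columns: the group keys, ``statistic``,
    ``estimate``, ``se``, ``ci_low``, ``ci_high``, ``n``, ``n_clusters``.
    Groups with fewer than 2 clusters get a missing SE rather than an error.
    """
    if design is None:
        df, design = _srs_frame(df)
    statistic = statistic or value_col
    levels = [sorted(df[g].unique()) for g in groups]
    rows = []
    grouped = dict(tuple(df.groupby(list(groups), sort=True, observed=True)))
    for combo in product(*levels):
        sub = grouped.get(combo)
        if sub is None and len(combo) == 1:  # pandas may key 1-col groupbys by scalar
            sub = grouped.get(combo[0])
        row = dict(zip(groups, combo))
        row["statistic"] = statistic
        if sub is None or sub.empty:
            row.update(
                estimate=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                n=0, n_clusters=0,
            )
            rows.append(row)
            continue
        vals = pd.to_numeric(sub[value_col], errors="coerce").to_numpy(dtype=float)
        wts = sub[design.weight].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        est = weighted_mean(vals, wts)
        n_clusters = int(sub.loc[ok, design.cluster].nunique())
        if ok.sum() == 0:
            se = np.nan
        else:
            try:
                se = linearized_se(
                    vals,
                    sub[design.stratum].to_numpy(),
                    sub[design.cluster].to_numpy(),
                    wts,
                    single_psu=design.single_psu,
                )
            except DegenerateDesignError:
                logger.warning(
                    "group %s: fewer than 2 clusters, SE not estimable", combo
                )
                se = np.nan
        row.update(
            estimate=est,
            se=se,
            ci_low=est - z * se if np.isfinite(se) else np.nan,
            ci_high=est + z * se if np.isfinite(se) else np.nan,
            n=int(ok.sum()),
            n_clusters=n_clusters,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(list(groups), kind="stable").reset_index(drop=True)
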