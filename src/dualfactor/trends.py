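"""Temporal trajectories of gender-age groups in the Dual Factor frame.

Each (gender, age) group contributes one trajectory: its design-based
(PHC mean, LS mean) point per survey wave, the quadrant that point falls in,
and the "jumps" — pairs of consecutive waves whose mean points lie in
different quadrants.  Jumps are declared from point estimates, with the
per-axis confidence intervals reported alongside; waves are repeated
cross-sections and treated as independent samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classification import CutoffPair, DEFAULT_CUTOFFS, Quadrant, classify
from .errors import ValidationError
from .survey import Z_95

Jump = Tuple[str, str, str, str]  # wave_from, wave_to, quadrant_from, quadrant_to


@dataclass
class Trajectory:
    """One group's path through the (PHC, LS) plane across waves."""

    gender: str
    age_group: int
    waves: List[str]
    phc_mean: List[float]
    phc_ci: List[Tuple[float, float]]
    ls_mean: List[float]
    ls_ci: List[Tuple[float, float]]
    quadrants: List[Optional[str]]
    jumps: List[Jump] = field(default_factory=list)


def _pivot(estimates: pd.DataFrame, statistic: str) -> pd.DataFrame:
    sub = estimates[estimates["statistic"] == statistic]
    if sub.empty:
        raise ValidationError(f"no rows with statistic {statistic!r} in estimates")
    return sub.set_index(["gender", "age_group", "wave"])


def build_trajectories(
    estimates: pd.DataFrame,
    cutoffs: CutoffPair = DEFAULT_CUTOFFS,
    waves: Optional[Sequence[str]] = None,
    phc_statistic: str = "phc",
    ls_statistic: str = "ls",
) -> List[Trajectory]:
    """Assemble per-group trajectories from a long table of group estimates.

    ``estimates`` is the output of :func:`dualfactor.survey.group_estimates`
    stacked for the PHC and LS statistics.  Mean points are classified with
    the same rule as individual respondents; a wave whose PHC or LS estimate
    is missing leaves a gap, and no jump is inferred across a gap.
    Output order is deterministic: gender, then age group; waves ascending.
    """
    phc = _pivot(estimates, phc_statistic)
    ls = _pivot(estimates, ls_statistic)
    if waves is None:
        waves = sorted(estimates["wave"].unique())
    waves = [str(w) for w in waves]
    groups = sorted(
        {(g, int(a)) for g, a, _ in phc.index} | {(g, int(a)) for g, a, _ in ls.index}
    )
    out: List[Trajectory] = []
    for gender, age in groups:
        phc_mean, phc_ci, ls_mean, ls_ci, quadrants = [], [], [], [], []
        for wave in waves:
            p = phc["estimate"].get((gender, age, wave), np.nan)
            l = ls["estimate"].get((gender, age, wave), np.nan)
            phc_mean.append(float(p))
            ls_mean.append(float(l))
            phc_ci.append(
                (
                    float(phc["ci_low"].get((gender, age, wave), np.nan)),
                    float(phc["ci_high"].get((gender, age, wave), np.nan)),
                )
            )
            ls_ci.append(
                (
                    float(ls["ci_low"].get((gender, age, wave), np.nan)),
                    float(ls["ci_high"].get((gender, age, wave), np.nan)),
                )
            )
            q = classify(l, p, cutoffs)
            quadrants.append(q.value if q is not None else None)
        jumps: List[Jump] = []
        for i in range(len(waves) - 1):
            q_from, q_to = quadrants[i], quadrants[i + 1]
            if q_from is not None and q_to is not None and q_from != q_to:
                jumps.append((waves[i], waves[i + 1], q_from, q_to))
        out.append(
            Trajectory(
                gender=gender,
                age_group=age,
                waves=list(waves),
                phc_mean=phc_mean,
                phc_ci=phc_ci,
                ls_mean=ls_mean,
                ls_ci=ls_ci,
                quadrants=quadrants,
                jumps=jumps,
            )
        )
    return out


def trajectories_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Long, plotting-ready table: one row per (group, wave)."""
    rows = []
    for t in trajectories:
        for i, wave in enumerate(t.waves):
            rows.append(
                {
                    "gender": t.gender,
                    "age_group": t.age_group,
                    "wave": wave,
                    "phc_mean": t.phc_mean[i],
                    "phc_ci_low": t.phc_ci[i][0],
                    "phc_ci_high": t.phc_ci[i][1],
                    "ls_mean": t.ls_mean[i],
                    "ls_ci_low": t.ls_ci[i][0],
                    "ls_ci_high": t.ls_ci[i][1],
                    "quadrant": t.quadrants[i],
                }
            )
    return pd.DataFrame(rows)


def mean_shift(
    estimates: pd.DataFrame,
    wave_a: str,
    wave_b: str,
    statistic: str = "phc",
    z: float = Z_95,
) -> pd.DataFrame:
    """Per-group change in a design-based mean between two waves.

    The difference is ``estimate(wave_b) - estimate(wave_a)``; its SE is
    ``sqrt(se_a^2 + se_b^2)`` under independence of the repeated
    cross-sections, with a normal CI.  Antisymmetric in the wave order.
    """
    wave_a, wave_b = str(wave_a), str(wave_b)
    table = _pivot(estimates, statistic)
    waves_present = {w for _, _, w in table.index}
    for w in (wave_a, wave_b):
        if w not in waves_present:
            raise ValidationError(f"wave {w!r} absent from estimates")
    rows = []
    groups = sorted({(g, int(a)) for g, a, _ in table.index})
    for gender, age in groups:
        try:
            a = table.loc[(gender, age, wave_a)]
            b = table.loc[(gender, age, wave_b)]
        except KeyError:
            raise ValidationError(
                f"group ({gender}, {age}) missing wave {wave_a!r} or {wave_b!r}"
            )
        diff = float(b["estimate"] - a["estimate"])
        se = float(np.hypot(a["se"], b["se"]))
        rows.append(
            {
                "gender": gender,
                "age_group": age,
                "statistic": statistic,
                "wave_from": wave_a,
                "wave_to": wave_b,
                "difference": diff,
                "se": se,
                "ci_low": diff - z * se,
                "ci_high": diff + z * se,
            }
        )
    return pd.DataFrame(rows)
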