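"""Model/Results front end tying the analysis stages together.

:class:`DualFactorModel` holds respondent-level data plus the analysis
conventions (cutoffs, survey design, grouping); :meth:`DualFactorModel.fit`
scores the items, runs the ROC sensitivity analysis of the symptom-score
cutoff, computes design-based group means and quadrant proportions, and
assembles the temporal trajectories.  The returned
:class:`DualFactorResults` carries every table with its uncertainty and
renders a text summary.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import calibration as _calibration
from . import classification as _classification
from . import io as _io
from . import scoring as _scoring
from . import simulate as _simulate
from . import survey as _survey
from . import trends as _trends
from .classification import CutoffPair, DEFAULT_CUTOFFS
from .errors import DegenerateInputError
from .survey import DEFAULT_GROUPS, SurveyDesign


class DualFactorModel:
    """Dual Factor analysis of a respondent-level survey table.

    Parameters
    ----------
    data
        Respondent table with the canonical columns (see
        :mod:`dualfactor.io`); may already contain scored columns, which are
        recomputed on fit.
    design
        Survey design column mapping; ``None`` analyses the data as an
        equal-weight simple random sample.
    cutoffs
        Classification cutoffs and boundary conventions.
    groups
        Stratification columns of all reported tables.
    min_items
        Minimum answered items for a symptom score (4 = complete case).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        design: Optional[SurveyDesign] = SurveyDesign(),
        cutoffs: CutoffPair = DEFAULT_CUTOFFS,
        groups: Sequence[str] = DEFAULT_GROUPS,
        min_items: int = 4,
    ):
        self.data = data.reset_index(drop=True)
        self.design = design
        self.cutoffs = cutoffs
        self.groups = tuple(groups)
        self.min_items = min_items

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DualFactorModel":
        """Build the model from a canonical respondent CSV file."""
        return cls(_io.read_respondents(path), **kwargs)

    @classmethod
    def from_generator(
        cls,
        config: Optional[_simulate.GeneratorConfig] = None,
        seed: Optional[int] = None,
        **kwargs,
    ) -> "DualFactorModel":
        """Build the model on a synthetic survey from the packaged generator."""
        if config is None:
            config = _simulate.default_config()
        return cls(_simulate.generate_survey(config, seed=seed), **kwargs)

    def fit(
        self,
        calibrate_cutoff: bool = False,
        selection_rule: str = "youden",
        weighted_roc: bool = False,
        n_boot: int = 0,
        seed: Optional[int] = None,
    ) -> "DualFactorResults":
        """Run the full analysis and return a results object.

        ``calibrate_cutoff=True`` replaces the configured symptom-score
        cutoff with the one selected by the ROC sweep before classifying;
        otherwise the sweep is reported as a sensitivity analysis only.
        ``n_boot > 0`` adds a percentile-bootstrap CI (clustered on the
        design's PSU column when a design is present) for the AUC.
        """
        scored = _scoring.score_frame(self.data, min_items=self.min_items)

        roc = cutoff_result = None
        try:
            roc = _calibration.roc_curve(
                scored["phc"],
                scored["gold"],
                weights=scored[self.design.weight] if (weighted_roc and self.design) else None,
            )
            ci = None
            if n_boot:
                ci = _calibration.auc_ci(
                    scored["phc"].to_numpy(),
                    scored["gold"].to_numpy(),
                    cluster=scored[self.design.cluster].to_numpy() if self.design else None,
                    n_boot=n_boot,
                    seed=seed,
                )
            cutoff_result = _calibration.select_cutoff(roc, rule=selection_rule, auc_ci=ci)
        except DegenerateInputError:
            pass  # single-class data: report no calibration

        cutoffs = self.cutoffs
        if calibrate_cutoff and cutoff_result is not None:
            cutoffs = dataclasses.replace(cutoffs, phc_cutoff=float(cutoff_result.cutoff))

        est_phc = _survey.group_estimates(
            scored, "phc", design=self.design, groups=self.groups, statistic="phc"
        )
        est_ls = _survey.group_estimates(
            scored, "ls_valid", design=self.design, groups=self.groups, statistic="ls"
        )
        estimates = pd.concat([est_phc, est_ls], ignore_index=True)
        quadrants = _classification.quadrant_distribution(
            scored, cutoffs, design=self.design, groups=self.groups
        )
        trajectories = _trends.build_trajectories(estimates, cutoffs)
        return DualFactorResults(
            model=self,
            scored=scored,
            cutoffs=cutoffs,
            roc=roc,
            cutoff_result=cutoff_result,
            group_estimates=estimates,
            quadrant_proportions=quadrants,
            trajectories=trajectories,
        )


class DualFactorResults:
    """Fitted tables of a Dual Factor analysis (see :class:`DualFactorModel`)."""

    def __init__(
        self,
        model: DualFactorModel,
        scored: pd.DataFrame,
        cutoffs: CutoffPair,
        roc,
        cutoff_result,
        group_estimates: pd.DataFrame,
        quadrant_proportions: pd.DataFrame,
        trajectories: List[_trends.Trajectory],
    ):
        self.model = model
        self.scored = scored
        self.cutoffs = cutoffs
        self.roc = roc
        self.cutoff_result = cutoff_result
        self.group_estimates = group_estimates
        self.quadrant_proportions = quadrant_proportions
        self.trajectories = trajectories

    @property
    def nobs(self) -> int:
        return len(self.scored)

    @property
    def jumps(self) -> List[tuple]:
        """All quadrant jumps, flattened: (gender, age, wave pair, quadrants)."""
        out = []
        for t in self.trajectories:
            for j in t.jumps:
                out.append((t.gender, t.age_group, *j))
        return out

    def mean_shift(self, wave_a, wave_b, statistic="phc") -> pd.DataFrame:
        """Per-group change of a mean between two waves (normal CI)."""
        return _trends.mean_shift(self.group_estimates, wave_a, wave_b, statistic)

    def mean_table(self, statistic: str = "phc") -> pd.DataFrame:
        """Wide mean table: rows = wave, columns = gender x age group."""
        sub = self.group_estimates[self.group_estimates["statistic"] == statistic]
        return sub.pivot_table(
            index="wave", columns=["gender", "age_group"], values="estimate"
        )

    def summary(self) -> str:
        """Plain-text account of the fitted tables."""
        lines = []
        lines.append("Dual Factor Model of adolescent mental well-being")
        lines.append("=" * 58)
        lines.append(f"Observations: {self.nobs}")
        lines.append(
            f"LS cutoff: {'>=' if self.cutoffs.ls_inclusive else '>'}"
            f"{self.cutoffs.ls_cutoff:g}   "
            f"PHC cutoff: {'>=' if self.cutoffs.phc_inclusive else '>'}"
            f"{self.cutoffs.phc_cutoff:g}"
        )
        if self.cutoff_result is not None:
            c = self.cutoff_result
            auc_txt = f"{c.auc:.3f}"
            if c.auc_ci is not None:
                auc_txt += f" (95% CI {c.auc_ci[0]:.3f}; {c.auc_ci[1]:.3f})"
            lines.append(
                f"ROC sensitivity analysis ({c.selection_rule}): cutoff {c.cutoff}, "
                f"sens {100 * c.sensitivity:.1f}% "
                f"({100 * c.sensitivity_ci[0]:.1f}; {100 * c.sensitivity_ci[1]:.1f}), "
                f"spec {100 * c.specificity:.1f}% "
                f"({100 * c.specificity_ci[0]:.1f}; {100 * c.specificity_ci[1]:.1f}), "
                f"AUC {auc_txt}"
            )
        lines.append("")
        lines.append("Group means (design-based 95% CI)")
        lines.append("-" * 58)
        sub = self.group_estimates.copy()
        sub["mean (95% CI)"] = sub.apply(
            lambda r: f"{r['estimate']:.2f} ({r['ci_low']:.2f}; {r['ci_high']:.2f})"
            if np.isfinite(r["estimate"]) and np.isfinite(r["se"])
            else "--",
            axis=1,
        )
        table = sub.pivot_table(
            index=[*self.model.groups],
            columns="statistic",
            values="mean (95% CI)",
            aggfunc="first",
        )
        lines.append(table.to_string())
        lines.append("")
        lines.append("Mean-point quadrants and jumps")
        lines.append("-" * 58)
        for t in self.trajectories:
            path = " -> ".join(q if q else "?" for q in t.quadrants)
            lines.append(f"{t.gender}/{t.age_group}: {path}")
            for j in t.jumps:
                lines.append(f"    jump {j[0]}->{j[1]}: {j[2]} -> {j[3]}")
        return "\n".join(lines)

    def plot_trajectories(self, ax=None, savefig=None):
        """Plot group mean trajectories in the (PHC, LS) plane.

        Draws the two cutoff lines partitioning the plane into the four
        states and one labelled path per gender-age group.
        """
        import matplotlib

        if savefig is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        ax.axvline(self.cutoffs.phc_cutoff, color="grey", lw=1, ls="--")
        ax.axhline(self.cutoffs.ls_cutoff, color="grey", lw=1, ls="--")
        for t in self.trajectories:
            ok = [i for i in range(len(t.waves)) if np.isfinite(t.phc_mean[i])]
            x = [t.phc_mean[i] for i in ok]
            y = [t.ls_mean[i] for i in ok]
            (line,) = ax.plot(x, y, marker="o", label=f"{t.gender} {t.age_group}")
            for i in ok:
                ax.annotate(
                    t.waves[i],
                    (t.phc_mean[i], t.ls_mean[i]),
                    fontsize=7,
                    color=line.get_color(),
                )
        ax.set_xlabel("PHC mean (0-16)")
        ax.set_ylabel("LS mean (0-10)")
        ax.legend(fontsize=8)
        if savefig is not None:
            ax.figure.savefig(savefig, dpi=150, bbox_inches="tight")
        return ax
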