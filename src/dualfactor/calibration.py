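"""ROC-based calibration of a cutoff on the continuous 0-16 PHC scale.

The continuous symptom score has no recommended clinical cutoff, so one is
established by a sensitivity analysis: the score is evaluated as a test for
the dichotomous gold standard ">= 2 symptoms more than once a week", sweeping
every threshold on the 0-16 scale.  A respondent is test-positive when their
score is at or above the threshold.  The operating threshold is chosen by
maximising the Youden index J = sensitivity + specificity - 1 (an alternative
closest-to-top-left-corner rule is available); AUC uses the trapezoidal rule
and its confidence interval a percentile bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

#: Thresholds swept on the 0-16 score: 0 (everyone positive) .. 17 (nobody).
DEFAULT_THRESHOLDS = tuple(range(18))

SELECTION_RULES = ("youden", "corner")


@dataclass
class RocCurve:
    """A full threshold sweep of the score against the gold standard."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    #: unweighted true-positive / true-negative counts per threshold,
    #: kept for exact binomial confidence intervals.
    tp: np.ndarray = field(repr=False, default=None)
    tn: np.ndarray = field(repr=False, default=None)
    weighted: bool = False


@dataclass
class CutoffResult:
    """The selected operating threshold and its diagnostic performance."""

    cutoff: int
    sensitivity: float
    sensitivity_ci: Tuple[float, float]
    specificity: float
    specificity_ci: Tuple[float, float]
    auc: float
    auc_ci: Optional[Tuple[float, float]]
    selection_rule: str


def _clean(scores, labels, weights):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have the same length")
    if weights is None:
        weights = np.ones_like(scores)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != scores.shape:
            raise ValidationError("weights must match scores in length")
        if np.any(weights[np.isfinite(weights)] <= 0):
            raise ValidationError("weights must be positive")
    keep = np.isfinite(scores) & np.isfinite(labels) & np.isfinite(weights)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("roc_curve: dropped %d pairs with missing score/label", n_dropped)
    return scores[keep], labels[keep] > 0.5, weights[keep]


def roc_curve(scores, labels, weights=None, thresholds=DEFAULT_THRESHOLDS) -> RocCurve:
    """Sweep thresholds over the score; test-positive means score >= threshold.

    Sensitivity is the (weighted) fraction of gold-positives that test
    positive; specificity the fraction of gold-negatives that test negative.
    AUC integrates the (1 - specificity, sensitivity) curve by the
    trapezoidal rule, which for an exhaustive threshold grid equals the
    Mann-Whitney concordance P(score_pos > score_neg) + 0.5 P(tie).
    """
    scores, pos, w = _clean(scores, labels, weights)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0:
        raise DegenerateInputError("no gold-positive observations in input")
    if n_neg == 0:
        raise DegenerateInputError("no gold-negative observations in input")
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    ge = scores[None, :] >= thresholds[:, None]  # (T, n)
    w_pos = w * pos
    w_neg = w * (~pos)
    sens = (ge * w_pos[None, :]).sum(axis=1) / w_pos.sum()
    spec = ((~ge) * w_neg[None, :]).sum(axis=1) / w_neg.sum()
    tp = (ge & pos[None, :]).sum(axis=1)
    tn = ((~ge) & (~pos)[None, :]).sum(axis=1)
    # traverse thresholds downward: fpr and sens are then both non-decreasing,
    # giving the ROC polyline in proper orientation (ties handled correctly)
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        tp=tp,
        tn=tn,
        weighted=weights is not None,
    )


def proportion_ci(k: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Two-sided Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValidationError("k must be in 0..n")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def select_cutoff(
    curve: RocCurve,
    rule: str = "youden",
    auc_ci: Optional[Tuple[float, float]] = None,
) -> CutoffResult:
    """Choose the operating threshold from a ROC sweep.

    ``youden`` maximises J = sensitivity + specificity - 1; ``corner``
    minimises the Euclidean distance to the (0, 1) corner of the ROC plane.
    Ties are broken toward the lower threshold.
    """
    if rule not in SELECTION_RULES:
        raise ValidationError(f"unknown selection rule {rule!r}; use one of {SELECTION_RULES}")
    if rule == "youden":
        objective = curve.sensitivity + curve.specificity - 1.0
    else:
        objective = -np.hypot(1.0 - curve.sensitivity, 1.0 - curve.specificity)
    idx = int(np.argmax(objective))  # thresholds ascending -> first max is lowest
    sens = float(curve.sensitivity[idx])
    spec = float(curve.specificity[idx])
    if curve.tp is not None:
        sens_ci = proportion_ci(int(curve.tp[idx]), curve.n_pos)
        spec_ci = proportion_ci(int(curve.tn[idx]), curve.n_neg)
    else:  # pragma: no cover - curves always carry counts
        sens_ci = spec_ci = (float("nan"), float("nan"))
    return CutoffResult(
        cutoff=int(curve.thresholds[idx]),
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        auc=curve.auc,
        auc_ci=auc_ci,
        selection_rule=rule,
    )


def auc_ci(
    scores,
    labels,
    weights=None,
    cluster=None,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    max_redraws: int = 1000,
) -> Tuple[float, float]:
    """Percentile-bootstrap confidence interval for the trapezoidal AUC.

    Resamples respondents with replacement, or whole clusters when ``cluster``
    ids are given (appropriate for class-sampled survey data).  Resamples that
    contain a single outcome class are redrawn, up to ``max_redraws`` extra
    draws in total; if the cap is hit the interval is computed from the
    replicates obtained so far, with a warning.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    if cluster is not None:
        cluster = np.asarray(cluster)
        unique = np.unique(cluster)
        members = {c: np.flatnonzero(cluster == c) for c in unique}
    aucs = []
    redraws = 0
    while len(aucs) < n_boot:
        if cluster is None:
            idx = rng.integers(len(scores), size=len(scores))
        else:
            picked = rng.integers(len(unique), size=len(unique))
            idx = np.concatenate([members[unique[p]] for p in picked])
        try:
            curve = roc_curve(
                scores[idx], labels[idx], None if weights is None else weights[idx]
            )
        except DegenerateInputError:
            redraws += 1
            if redraws > max_redraws:
                warnings.warn(
                    "auc_ci: redraw cap reached; interval based on "
                    f"{len(aucs)} replicates",
                    stacklevel=2,
                )
                break
            continue
        aucs.append(curve.auc)
    if not aucs:
        raise DegenerateInputError("all bootstrap resamples were single-class")
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
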