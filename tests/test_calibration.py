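"""ROC sweep, cutoff selection, and confidence intervals."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import dualfactor as dfm
from conftest import random_roc_dataset, small_generator_config


def mann_whitney_concordance(scores, labels):
    """Brute-force pairwise P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).mean()
    eq = (pos[:, None] == neg[None, :]).mean()
    return gt + 0.5 * eq


def brute_force_youden(scores, labels, thresholds=range(18)):
    """Independent sweep: J at every threshold, lowest argmax."""
    best_t, best_j = None, -np.inf
    pos, neg = labels == 1, labels == 0
    for t in thresholds:
        sens = (scores[pos] >= t).mean()
        spec = (scores[neg] < t).mean()
        j = sens + spec - 1
        if j > best_j:
            best_t, best_j = t, j
    return best_t


class TestRocCurve:
    def test_perfect_separation(self):
        curve = dfm.roc_curve([9, 10, 3, 4], [1, 1, 0, 0])
        assert curve.auc == 1.0

    def test_complete_overlap(self):
        curve = dfm.roc_curve([5, 5], [1, 0])
        assert curve.auc == 0.5

    def test_endpoints(self):
        rng = np.random.default_rng(0)
        scores, labels = random_roc_dataset(rng)
        curve = dfm.roc_curve(scores, labels)
        assert curve.sensitivity[0] == 1.0 and curve.specificity[0] == 0.0
        assert curve.sensitivity[-1] == 0.0 and curve.specificity[-1] == 1.0

    def test_mann_whitney_equivalence_and_monotonicity(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            scores, labels = random_roc_dataset(rng)
            curve = dfm.roc_curve(scores, labels)
            assert curve.auc == pytest.approx(
                mann_whitney_concordance(scores, labels), abs=1e-12
            )
            assert (np.diff(curve.sensitivity) <= 1e-15).all()
            assert (np.diff(curve.specificity) >= -1e-15).all()

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            scores, labels = random_roc_dataset(rng)
            curve = dfm.roc_curve(scores, labels)
            assert curve.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_raises_naming_missing_class(self):
        with pytest.raises(dfm.DegenerateInputError, match="negative"):
            dfm.roc_curve([1, 2], [1, 1])
        with pytest.raises(dfm.DegenerateInputError, match="positive"):
            dfm.roc_curve([1, 2], [0, 0])

    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(5)
        scores, labels = random_roc_dataset(rng)
        a = dfm.roc_curve(scores, labels)
        b = dfm.roc_curve(scores, labels, weights=np.full(len(scores), 2.5))
        assert np.array_equal(a.sensitivity, b.sensitivity)
        assert np.array_equal(a.specificity, b.specificity)
        assert a.auc == b.auc

    def test_missing_pairs_dropped(self):
        curve = dfm.roc_curve(
            [9, 10, 3, 4, np.nan, 2], [1, 1, 0, 0, 0, np.nan]
        )
        assert curve.n_pos == 2 and curve.n_neg == 2
        assert curve.auc == 1.0


class TestSelectCutoff:
    def test_unique_maximum(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.integers(8, 17, 30), rng.integers(0, 8, 30)])
        labels = np.concatenate([np.ones(30), np.zeros(30)])
        curve = dfm.roc_curve(scores, labels)
        assert dfm.select_cutoff(curve).cutoff == brute_force_youden(scores, labels)

    def test_brute_force_agreement_random(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            scores, labels = random_roc_dataset(rng)
            curve = dfm.roc_curve(scores, labels)
            result = dfm.select_cutoff(curve, rule="youden")
            assert result.cutoff == brute_force_youden(scores, labels)
            assert result.selection_rule == "youden"

    def test_tie_breaks_to_lower_threshold(self):
        # all positives at 10, all negatives at 2: every threshold in 3..10
        # has J = 1; the lowest (3) must be selected
        curve = dfm.roc_curve([10, 10, 2, 2], [1, 1, 0, 0])
        assert dfm.select_cutoff(curve).cutoff == 3

    def test_corner_rule_available_and_labelled(self):
        rng = np.random.default_rng(3)
        scores, labels = random_roc_dataset(rng)
        result = dfm.select_cutoff(dfm.roc_curve(scores, labels), rule="corner")
        assert result.selection_rule == "corner"
        assert 0 <= result.cutoff <= 17

    def test_double_implementation_on_synthetic_default(self):
        scored = dfm.score_frame(
            dfm.generate_survey(small_generator_config(n_per_cell=800, seed=13))
        )
        ok = scored["phc"].notna() & scored["gold"].notna()
        scores = scored.loc[ok, "phc"].to_numpy()
        labels = scored.loc[ok, "gold"].to_numpy()
        result = dfm.select_cutoff(dfm.roc_curve(scores, labels))
        assert result.cutoff == brute_force_youden(scores, labels)

    def test_cis_contain_point_estimates(self):
        rng = np.random.default_rng(21)
        scores, labels = random_roc_dataset(rng)
        r = dfm.select_cutoff(dfm.roc_curve(scores, labels))
        assert r.sensitivity_ci[0] <= r.sensitivity <= r.sensitivity_ci[1]
        assert r.specificity_ci[0] <= r.specificity <= r.specificity_ci[1]

    def test_unknown_rule_rejected(self):
        curve = dfm.roc_curve([9, 3], [1, 0])
        with pytest.raises(dfm.ValidationError):
            dfm.select_cutoff(curve, rule="accuracy")


class TestProportionCi:
    def test_boundaries(self):
        assert dfm.proportion_ci(10, 10)[1] == 1.0
        assert dfm.proportion_ci(0, 10)[0] == 0.0

    def test_wilson_closed_form(self):
        # hand evaluation of the Wilson score interval for k=8, n=10
        k, n, z = 8, 10, 1.959963984540054
        p = k / n
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (
            z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        )
        lo, hi = dfm.proportion_ci(k, n)
        assert lo == pytest.approx(centre - half, abs=1e-10)
        assert hi == pytest.approx(centre + half, abs=1e-10)

    @pytest.mark.parametrize("k,n", [(1, 0), (-1, 5), (6, 5)])
    def test_domain_errors(self, k, n):
        with pytest.raises(dfm.ValidationError):
            dfm.proportion_ci(k, n)


class TestAucCi:
    def test_perfect_separation_collapses(self):
        scores = np.r_[np.full(30, 12.0), np.full(30, 2.0)]
        labels = np.r_[np.ones(30), np.zeros(30)]
        assert dfm.auc_ci(scores, labels, n_boot=100, seed=1) == (1.0, 1.0)

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(11)
        scores = np.r_[rng.normal(9, 3, 80), rng.normal(5, 3, 80)].clip(0, 16)
        labels = np.r_[np.ones(80), np.zeros(80)]
        point = dfm.roc_curve(scores, labels).auc
        lo, hi = dfm.auc_ci(scores, labels, n_boot=300, seed=2)
        assert lo <= point <= hi

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(4)
        scores, labels = random_roc_dataset(rng)
        a = dfm.auc_ci(scores, labels, n_boot=150, seed=42)
        b = dfm.auc_ci(scores, labels, n_boot=150, seed=42)
        assert a == b

    def test_width_shrinks_with_sample_size(self):
        widths = {}
        for n, seed in ((500, 6), (50_000, 7)):
            rng = np.random.default_rng(seed)
            half = n // 2
            scores = np.rint(
                np.r_[rng.normal(9, 3, half), rng.normal(6, 3, half)].clip(0, 16)
            )
            labels = np.r_[np.ones(half), np.zeros(half)]
            lo, hi = dfm.auc_ci(scores, labels, n_boot=200, seed=seed)
            widths[n] = hi - lo
        ratio = widths[50_000] / widths[500]
        # expected ~ sqrt(500/50000) = 0.1
        assert 0.03 < ratio < 0.35

    def test_small_n_boot_rejected(self):
        with pytest.raises(dfm.ValidationError):
            dfm.auc_ci([9, 3], [1, 0], n_boot=10)
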