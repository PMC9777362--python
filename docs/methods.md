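# Methods

This note documents the statistical content of the package: the scales and
rules it implements, the generative model behind the synthetic surveys, the
estimators, and the design choices made where conventions were open.

## Scales and scoring

The four psychological symptom items (feeling low, irritability,
nervousness, sleep difficulty) arrive coded 1 = "about every day" …
5 = "rarely/never". Scoring reverses and rescales each to 0–4
(0 = "rarely/never" … 4 = "about every day") and sums them into the 0–16
PHC score; higher means more frequent and intense complaints. The ladder
item (LS) is passed through when it is an integer in 0–10 and treated as
missing otherwise, with a logged count.

**Missing items.** The sum scale is scored complete-case: any missing item
blanks the score and the gold-standard label. With only four items a
prorated sum is hard to defend as a default, but a `min_items` switch is
exposed; when fewer than four items are accepted the partial sum is scaled
by `4 / n_answered` and rounded. The label is blanked on any missing item
because an unanswered item could change the qualifying-symptom count in
either direction.

**Gold standard.** "≥ 2 symptoms more than once a week" is read as at
least two items with rescaled score ≥ 3, i.e. "more than once a week"
*includes* "about every day". Any other reading makes the criterion
non-monotone in symptom frequency. A consequence used by the tests: every
gold-positive pattern has PHC ≥ 6, so ROC sensitivity is exactly 1 at all
thresholds ≤ 6.

## Cutoff calibration

The ROC sweeps thresholds 0–17 with test-positive defined as score ≥
threshold, so threshold 0 is the all-positive corner and 17 the
all-negative one. AUC is the trapezoidal integral of the
(1 − specificity, sensitivity) polyline, traversed in descending threshold
order so ties in the false-positive rate are handled correctly; on this
exhaustive grid it equals the Mann–Whitney concordance
P(score⁺ > score⁻) + ½ P(tie), which the tests verify to 1e-12 against a
pairwise brute force and scikit-learn.

Open conventions and how they were fixed:

- **Selection rule.** "Maximising the ROC curve" is operationalised as the
  Youden index, the conventional scalar criterion; a
  closest-to-(0, 1)-corner rule is available, and the rule used is recorded
  in every output. Ties break toward the lower threshold (favouring
  sensitivity, the screening-friendly direction).
- **Positivity at the cutoff.** Score ≥ cutoff counts as positive, matching
  the "high PHC" classification convention downstream.
- **Sensitivity/specificity CIs** are Wilson score intervals (bounded,
  good small-sample behaviour) on the unweighted counts.
- **AUC CI** is a seeded percentile bootstrap — resampling respondents, or
  whole school classes when a design is present — rather than DeLong, so
  one mechanism serves weighted and clustered data alike. Single-class
  resamples are redrawn up to a capped number of extra draws.
- The ROC is unweighted by default with a flag to apply design weights;
  equal weights reproduce the unweighted sweep exactly.

## Classification

High LS is LS ≥ 6 (protocol cutoff); high PHC is PHC ≥ 8 by default or the
ROC-selected cutoff when calibration is applied. Both boundaries are
inclusive by default and both conventions are explicit config fields
recorded in the run manifest, since inclusivity is a genuine ambiguity:
the point (LS 6, PHC 8) classifies as Struggling under the defaults. Group
*means* are classified with the same real-valued rule, which is what places
trajectories in the frame.

## Survey estimation

Point estimates are Hajek weighted means. Variances use Taylor
linearisation with school classes as with-replacement PSUs within strata
and no finite-population correction — the standard default when sampling
fractions are unknown. For stratum *h* with PSU totals
z_hj = Σ_i w_i (y_i − ŷ)/Σ w the contribution is
n_h/(n_h − 1) · Σ_j (z_hj − z̄_h)². In the degenerate design (one stratum,
one respondent per PSU, equal weights) this reduces *exactly* to the
classic s/√n with the 1/(n − 1) sample variance. Lone-PSU strata
contribute squared deviations from the grand PSU mean (documented,
switchable to collapsing them into a pseudo-stratum). Missing values are
dropped pairwise per statistic with logged counts; PSUs with no observed
value for a statistic drop out of its variance. Confidence intervals are
normal-reference (±1.96 SE), matching the symmetric intervals such surveys
print. Estimates and SEs are invariant to rescaling all weights by a
constant.

A simulation check (part of the test suite) confirms ~95% coverage of the
generator's analytic cell means: 93.9% observed over 300 replicate
surveys of 6 cells each at 40 classes per age layer — the small deficit
versus nominal is the usual z-versus-t effect at ~40 PSUs.

## Trend analysis

Waves are repeated cross-sections and treated as independent, so a
between-wave mean difference has SE √(SE_a² + SE_b²). Quadrant jumps are
declared from point estimates of the means — the frame is descriptive, and
no formal test of region membership is attempted — with per-axis CIs
reported alongside. A wave with a missing estimate leaves a gap, and no
jump is inferred across a gap.

## The synthetic generator

Real microdata of this kind are access-restricted, so the package
generates structurally faithful surveys. Respondent latent severity is
θ = μ(wave, gender, age) + b_class + e with b_class ~ N(0, cluster_sd²)
shared by classmates and e ~ N(0, sigma_theta²). Items follow a logistic
graded-response model, P(rescaled ≥ k) = logistic(a_i (θ − t_ik)), the
standard generative choice for 5-level symptom items; it gives closed-form
category probabilities, so every cell's expected PHC is computable by
Gauss–Hermite integration and serves as an independent oracle for the
Monte Carlo tests. The ladder is
LS = clip(round(ls_intercept + ls_shift(cell) − ls_slope·θ + ε), 0, 10),
linear in severity within a cell (so PHC and LS are negatively correlated
at the respondent level, r ≈ −0.3 under defaults) while the per-cell
shift lets cell-level LS move on its own trajectory. That freedom is not a
convenience: the phenomenon being modelled is precisely that symptom means
rise while life-satisfaction means stay flat, and girls and boys sit at
different LS levels for the same symptom load, which no single linear map
of severity can produce. Expected LS under rounding and clipping has a
closed form (a sum of normal-CDF differences), used both in calibration
and as the LS oracle.

**Calibration.** `default_config()` solves, per cell, μ such that the
analytic expected PHC equals the published target mean, then the ladder
shift such that expected LS equals its target — 36 one-dimensional root
findings. The targets (all 18 cells × both variables) are recorded in
`CALIBRATION_TARGETS`; e.g. 15-year-old girls' PHC targets are 7.5/8.6/9.1
across 2010/2014/2018 with LS 6.9/6.7/6.9.

**Fixed defaults and why.** Item discriminations (1.3, 1.1, 1.0, 0.9) and
staggered thresholds give a realistic right-skewed symptom-score
distribution (SD ≈ 4) and ~35% gold-positive prevalence near the
published mean levels; sigma_theta = 1 sets the latent scale;
cluster_sd = 0.10 yields a class-level intraclass correlation of ≈ 0.01
for the symptom score, consistent with the small classroom clustering of
self-reported psychological complaints; ls_slope = 0.55 and
ls_noise_sd = 1.5 give an LS SD ≈ 1.6; weight_cv = 0.3 mimics moderate
post-stratification weight dispersion (weights lognormal, mean-normalised
within wave — no claim to reproduce any country's actual design).
Classes are shared between genders within a (wave, stratum, age) layer,
as in mixed-gender classrooms; respondents are dealt round-robin so class
sizes are equal up to one. All randomness flows from one explicit seed;
identical config + seed is byte-reproducible.

**What the generator does not emulate.** Regional stratification effects,
nonresponse mechanisms, unequal class sizes, higher moments of the real
response distributions (only cell means are constrained), and any
dependence of weights on outcomes. Passing tests therefore demonstrate
correctness of the estimators and the qualitative reproducibility of the
trajectory findings under the stated structure — not properties of any
real population.

## Problem sizes

The test suite runs the end-to-end scenario at 5000 respondents per cell
(90,000 per survey, 20 replicate seeds), where one cell mean has Monte
Carlo SE ≈ 0.065 — so the ±0.2 tolerance on cell means is a 3-SE check —
and the coverage simulation at 300 surveys of 1800 respondents. The
acceptance script analyses one 90,000-respondent survey with a
200-replicate cluster bootstrap for the AUC.

## Known limitations

- The variance estimator assumes with-replacement PSU sampling; with large
  sampling fractions it is conservative.
- Normal CIs can undercover slightly with few PSUs (use more clusters or
  interpret accordingly); no replicate-weight (BRR/jackknife) methods.
- Jumps are point-estimate statements; two groups whose means hug a cutoff
  can jump on noise. The reported CIs make this visible but the package
  deliberately attaches no hypothesis test to region membership.
- The prorated `min_items < 4` score is a convenience, not a validated
  scale variant.
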