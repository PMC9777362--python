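"""Synthetic HBSC-like survey generator.

Emulates the structure of a repeated cross-sectional school survey of 11-,
13- and 15-year-olds: three waves, two genders, stratified cluster sampling
of school classes, post-stratification-style design weights, four 5-level
psychological symptom items and a 0-10 life-satisfaction ladder.

The generative model is a logistic graded-response (cumulative ordinal)
model.  Each respondent carries a latent symptom severity

    theta = mu(wave, gender, age) + b_class + e,
    b_class ~ N(0, cluster_sd^2),  e ~ N(0, sigma_theta^2),

and answers item *i* with rescaled score ``s`` in 0..4 according to

    P(s >= k) = logistic(a_i * (theta - t_{i,k})),  k = 1..4,

where ``a_i`` is the item discrimination and ``t_{i,1} < ... < t_{i,4}`` the
item thresholds.  Original codes are ``5 - s`` (1 = "about every day",
5 = "rarely/never").  The ladder score is a linear function of severity,

    ls = clip(round(ls_intercept + ls_shift(cell) - ls_slope * theta + eps), 0, 10),
    eps ~ N(0, ls_noise_sd^2),

so that well-being and symptom load are negatively related within a cell
while their cell means can move on separate trajectories across waves — the
empirical pattern (rising complaints, steady life satisfaction) the
generator is calibrated to.  Design weights are lognormal with a chosen
coefficient of variation, normalised to mean 1 within each wave.

Because the category probabilities are in closed form, the expected PHC and
LS of any cell can be computed by numerical integration over the latent
distribution (:func:`expected_phc`, :func:`expected_ls`); the packaged
default configuration (:func:`default_config`) inverts those expectations so
that every cell mean matches its published target (see ``CALIBRATION_TARGETS``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .errors import ConfigurationError, ValidationError
from .scoring import ITEM_COLUMNS

Cell = Tuple[str, str, int]

GENDERS = ("boy", "girl")
AGE_GROUPS = (11, 13, 15)
DEFAULT_WAVES = ("2010", "2014", "2018")

#: Published cell-mean targets the default configuration is calibrated to:
#: (wave, gender, age) -> (PHC mean on 0-16, LS mean on 0-10).
CALIBRATION_TARGETS: Dict[Cell, Tuple[float, float]] = {
    ("2010", "boy", 11): (5.1, 8.0),
    ("2014", "boy", 11): (5.0, 7.9),
    ("2018", "boy", 11): (5.9, 8.0),
    ("2010", "boy", 13): (5.2, 7.7),
    ("2014", "boy", 13): (5.3, 7.6),
    ("2018", "boy", 13): (6.0, 7.7),
    ("2010", "boy", 15): (5.7, 7.4),
    ("2014", "boy", 15): (5.8, 7.2),
    ("2018", "boy", 15): (6.4, 7.3),
    ("2010", "girl", 11): (5.3, 8.1),
    ("2014", "girl", 11): (5.5, 7.8),
    ("2018", "girl", 11): (6.4, 8.0),
    ("2010", "girl", 13): (6.6, 7.4),
    ("2014", "girl", 13): (7.7, 7.0),
    ("2018", "girl", 13): (8.2, 7.4),
    ("2010", "girl", 15): (7.5, 6.9),
    ("2014", "girl", 15): (8.6, 6.7),
    ("2018", "girl", 15): (9.1, 6.9),
}

_DEFAULT_DISCRIMINATIONS = (1.3, 1.1, 1.0, 0.9)
_DEFAULT_THRESHOLDS = (
    (-0.5, 0.4, 1.2, 2.1),  # feeling low
    (-0.9, 0.0, 0.9, 1.8),  # irritability
    (-1.1, -0.2, 0.8, 1.7),  # nervousness
    (-0.7, 0.3, 1.1, 2.0),  # sleep difficulty
)


def _canon_cell(key) -> Cell:
    wave, gender, age = key
    return (str(wave), str(gender), int(age))


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic survey generator.

    ``mu`` maps every (wave, gender, age) cell to its latent severity mean;
    ``ls_shift`` optionally offsets the ladder intercept per cell (default 0),
    which lets cell-level expected life satisfaction move independently of
    expected symptom load.
    """

    mu: Dict[Cell, float]
    n_per_cell: int = 1000
    waves: Tuple[str, ...] = DEFAULT_WAVES
    sigma_theta: float = 1.0
    item_discriminations: Tuple[float, ...] = _DEFAULT_DISCRIMINATIONS
    item_thresholds: Tuple[Tuple[float, ...], ...] = _DEFAULT_THRESHOLDS
    ls_intercept: float = 8.5
    ls_slope: float = 0.55
    ls_shift: Dict[Cell, float] = field(default_factory=dict)
    ls_noise_sd: float = 1.5
    n_strata: int = 8
    clusters_per_stratum: int = 5
    cluster_sd: float = 0.10
    weight_cv: float = 0.3
    seed: int = 0

    def __post_init__(self):
        self.waves = tuple(str(w) for w in self.waves)
        self.mu = {_canon_cell(k): float(v) for k, v in self.mu.items()}
        self.ls_shift = {_canon_cell(k): float(v) for k, v in self.ls_shift.items()}
        self.item_discriminations = tuple(float(a) for a in self.item_discriminations)
        self.item_thresholds = tuple(
            tuple(float(t) for t in row) for row in self.item_thresholds
        )
        self.validate()

    def validate(self) -> None:
        if int(self.n_per_cell) < 1:
            raise ConfigurationError("n_per_cell", "must be a positive count")
        if len(self.waves) < 1:
            raise ConfigurationError("waves", "at least one wave label required")
        if len(set(self.waves)) != len(self.waves):
            raise ConfigurationError("waves", "wave labels must be unique")
        if not self.sigma_theta > 0:
            raise ConfigurationError("sigma_theta", "must be > 0")
        if not self.ls_noise_sd > 0:
            raise ConfigurationError("ls_noise_sd", "must be > 0")
        if not self.cluster_sd > 0:
            raise ConfigurationError("cluster_sd", "must be > 0")
        if self.weight_cv < 0:
            raise ConfigurationError("weight_cv", "must be >= 0")
        if int(self.n_strata) < 1:
            raise ConfigurationError("n_strata", "must be a positive count")
        if int(self.clusters_per_stratum) < 1:
            raise ConfigurationError("clusters_per_stratum", "must be a positive count")
        if len(self.item_discriminations) != 4:
            raise ConfigurationError("item_discriminations", "exactly 4 values required")
        if any(a <= 0 for a in self.item_discriminations):
            raise ConfigurationError("item_discriminations", "must all be > 0")
        if len(self.item_thresholds) != 4:
            raise ConfigurationError("item_thresholds", "exactly 4 rows required")
        for i, row in enumerate(self.item_thresholds):
            if len(row) != 4:
                raise ConfigurationError(
                    "item_thresholds", f"item {i}: exactly 4 thresholds required"
                )
            if any(b <= a for a, b in zip(row, row[1:])):
                raise ConfigurationError(
                    "item_thresholds", f"item {i}: thresholds must be strictly increasing"
                )
        for cell in self.cells():
            if cell not in self.mu:
                raise ConfigurationError("mu", f"no latent mean for cell {cell}")
        for cell in self.ls_shift:
            if cell not in self.mu:
                raise ConfigurationError("ls_shift", f"unknown cell {cell}")

    def cells(self) -> Tuple[Cell, ...]:
        """All (wave, gender, age) cells in the fixed deterministic order."""
        return tuple(
            (w, g, a) for w in self.waves for g in GENDERS for a in AGE_GROUPS
        )

    @property
    def latent_sd(self) -> float:
        """Marginal SD of latent severity (individual + class components)."""
        return math.hypot(self.sigma_theta, self.cluster_sd)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mu"] = _nest_cells(self.mu, self.waves)
        d["ls_shift"] = _nest_cells(self.ls_shift, self.waves)
        d["item_thresholds"] = [list(row) for row in self.item_thresholds]
        d["item_discriminations"] = list(self.item_discriminations)
        d["waves"] = list(self.waves)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("mu", "ls_shift"):
            if key in d and isinstance(d[key], dict) and d[key]:
                first = next(iter(d[key].values()))
                if isinstance(first, dict):  # nested wave -> gender -> age form
                    d[key] = _flatten_cells(d[key])
        return cls(**d)

    def to_yaml(self, path=None) -> Optional[str]:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=None)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "GeneratorConfig":
        """Load a configuration from a YAML file path or a YAML string."""
        try:
            with open(source, "r", encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        except (OSError, TypeError):
            data = yaml.safe_load(source)
        if not isinstance(data, dict):
            raise ConfigurationError("config", "YAML document must be a mapping")
        return cls.from_dict(data)


def _nest_cells(mapping: Dict[Cell, float], waves) -> dict:
    out: dict = {}
    for (w, g, a), v in mapping.items():
        out.setdefault(str(w), {}).setdefault(str(g), {})[int(a)] = float(v)
    return out


def _flatten_cells(nested: dict) -> Dict[Cell, float]:
    flat: Dict[Cell, float] = {}
    for w, by_gender in nested.items():
        for g, by_age in by_gender.items():
            for a, v in by_age.items():
                flat[(str(w), str(g), int(a))] = float(v)
    return flat


# ---------------------------------------------------------------------------
# Analytic expectations (the generator's own oracle)
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)


def expected_phc_given_theta(config: GeneratorConfig, theta) -> np.ndarray:
    """E[PHC | theta] = sum over items and levels of P(rescaled >= k)."""
    theta = np.asarray(theta, dtype=float)
    total = np.zeros_like(theta)
    for a, thr in zip(config.item_discriminations, config.item_thresholds):
        for t in thr:
            total += expit(a * (theta - t))
    return total


def expected_phc(config: GeneratorConfig, cell, mu: Optional[float] = None) -> float:
    """Expected PHC of a cell, by Gauss-Hermite integration over theta.

    ``mu`` overrides the cell's latent mean when given (used by calibration).
    """
    cell = _canon_cell(cell)
    m = config.mu[cell] if mu is None else float(mu)
    sd = config.latent_sd
    theta = m + math.sqrt(2.0) * sd * _GH_NODES
    vals = expected_phc_given_theta(config, theta)
    return float(np.sum(_GH_WEIGHTS * vals) / math.sqrt(math.pi))


def expected_ls(config: GeneratorConfig, cell, shift: Optional[float] = None) -> float:
    """Expected ladder score of a cell, exact under rounding and clipping.

    The pre-rounding ladder value is Normal with mean
    ``ls_intercept + shift - ls_slope * mu`` and SD
    ``sqrt(ls_slope^2 * latent_var + ls_noise_sd^2)``; the expectation sums
    k * P(round/clip -> k) over k = 0..10.
    """
    cell = _canon_cell(cell)
    s = config.ls_shift.get(cell, 0.0) if shift is None else float(shift)
    m = config.ls_intercept + s - config.ls_slope * config.mu[cell]
    sd = math.hypot(config.ls_slope * config.latent_sd, config.ls_noise_sd)
    edges = np.arange(0.5, 10.0, 1.0)  # 0.5 .. 9.5
    cdf = norm.cdf((edges - m) / sd)
    probs = np.concatenate(([cdf[0]], np.diff(cdf), [1.0 - cdf[-1]]))
    return float(np.sum(np.arange(11) * probs))


# ---------------------------------------------------------------------------
# Default configuration calibrated to the published cell means
# ---------------------------------------------------------------------------

def default_config(n_per_cell: int = 1000, seed: int = 0) -> GeneratorConfig:
    """The packaged configuration, calibrated to ``CALIBRATION_TARGETS``.

    For each (wave, gender, age) cell the latent mean ``mu`` is solved so the
    analytic expected PHC equals the published PHC mean, and the ladder shift
    is solved so the analytic expected LS equals the published LS mean.  Item
    parameters, variance components and the weight CV are fixed package
    defaults (see docs/methods.md).
    """
    base = GeneratorConfig(
        mu={cell: 0.0 for cell in CALIBRATION_TARGETS},
        n_per_cell=n_per_cell,
        seed=seed,
    )
    mu: Dict[Cell, float] = {}
    for cell, (phc_target, _) in CALIBRATION_TARGETS.items():
        mu[cell] = brentq(
            lambda m: expected_phc(base, cell, mu=m) - phc_target, -6.0, 6.0, xtol=1e-10
        )
    cfg = dataclasses.replace(base, mu=mu)
    shift: Dict[Cell, float] = {}
    for cell, (_, ls_target) in CALIBRATION_TARGETS.items():
        shift[cell] = brentq(
            lambda s: expected_ls(cfg, cell, shift=s) - ls_target, -8.0, 8.0, xtol=1e-10
        )
    return dataclasses.replace(cfg, ls_shift=shift)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_survey(config: GeneratorConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate one synthetic survey as a respondent-level DataFrame.

    Deterministic given (config, seed); ``seed`` defaults to ``config.seed``.
    Columns: respondent_id, wave, age_group, gender, stratum, cluster,
    weight, the four item columns (original 1-5 codes) and ls.

    Respondents in a cell are dealt round-robin across the
    ``n_strata * clusters_per_stratum`` school classes of their (wave, age)
    layer; classes are shared between genders, as in a mixed-gender
    classroom, and carry a common latent random effect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    S, C = config.n_strata, config.clusters_per_stratum

    # class random effects, drawn in fixed (wave, stratum, age) order
    class_effects: Dict[Tuple[str, int, int], np.ndarray] = {}
    for w in config.waves:
        for s in range(S):
            for a in AGE_GROUPS:
                class_effects[(w, s, a)] = rng.normal(0.0, config.cluster_sd, size=C)

    disc = np.asarray(config.item_discriminations)
    thr = np.asarray(config.item_thresholds)
    frames = []
    for wave, gender, age in config.cells():
        n = int(config.n_per_cell)
        slot = np.arange(n) % (S * C)
        stratum_idx = slot // C
        cluster_idx = slot % C
        eff_grid = np.stack([class_effects[(wave, s, age)] for s in range(S)])
        theta = (
            config.mu[(wave, gender, age)]
            + eff_grid[stratum_idx, cluster_idx]
            + rng.normal(0.0, config.sigma_theta, size=n)
        )
        items = {}
        for j, col in enumerate(ITEM_COLUMNS):
            u = rng.uniform(size=n)
            p_ge = expit(disc[j] * (theta[:, None] - thr[j][None, :]))  # (n, 4)
            rescaled = (u[:, None] < p_ge).sum(axis=1)
            items[col] = 5 - rescaled  # original coding
        shift = config.ls_shift.get((wave, gender, age), 0.0)
        ls_star = (
            config.ls_intercept
            + shift
            - config.ls_slope * theta
            + rng.normal(0.0, config.ls_noise_sd, size=n)
        )
        ls = np.clip(np.rint(ls_star), 0, 10).astype(int)
        if config.weight_cv > 0:
            sig2 = math.log1p(config.weight_cv**2)
            weight = rng.lognormal(mean=-sig2 / 2.0, sigma=math.sqrt(sig2), size=n)
        else:
            weight = np.ones(n)
        frames.append(
            pd.DataFrame(
                {
                    "wave": wave,
                    "age_group": age,
                    "gender": gender,
                    "stratum": [f"{wave}-s{s + 1}" for s in stratum_idx],
                    "cluster": [
                        f"{wave}-s{s + 1}-a{age}-c{c + 1}"
                        for s, c in zip(stratum_idx, cluster_idx)
                    ],
                    "weight": weight,
                    **items,
                    "ls": ls,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    # normalise weights to mean 1 within wave
    df["weight"] = df["weight"] / df.groupby("wave")["weight"].transform("mean")
    df.insert(0, "respondent_id", [f"r{i + 1:07d}" for i in range(len(df))])
    return df


def inject_missingness(
    df: pd.DataFrame, item_rate: float, ls_rate: float, seed: int
) -> pd.DataFrame:
    """Independently blank each item response and ladder score at given rates."""
    for name, rate in (("item_rate", item_rate), ("ls_rate", ls_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {rate!r}")
    rng = np.random.default_rng(seed)
    out = df.copy()
    for col in (*ITEM_COLUMNS, "ls"):
        rate = ls_rate if col == "ls" else item_rate
        mask = rng.random(len(out)) < rate
        if mask.any():
            out[col] = out[col].astype(float).mask(mask)
    return out
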