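"""The synthetic survey generator and its analytic self-oracle."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import dualfactor as dfm
from dualfactor.scoring import ITEM_COLUMNS

from conftest import small_generator_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("sigma_theta", 0.0),
            ("ls_noise_sd", -1.0),
            ("cluster_sd", 0.0),
            ("weight_cv", -0.1),
            ("n_per_cell", 0),
            ("n_strata", 0),
            ("item_discriminations", (1.0, 1.0, 1.0, -1.0)),
            ("item_thresholds", ((0, 1, 1, 2),) * 4),
        ],
    )
    def test_invalid_field_is_named(self, field, value):
        with pytest.raises(dfm.ConfigurationError) as err:
            small_generator_config(**{field: value})
        assert field in str(err.value)

    def test_missing_cell_mean_rejected(self):
        with pytest.raises(dfm.ConfigurationError) as err:
            small_generator_config(mu={("2014", "boy", 11): 0.0})
        assert "mu" in str(err.value)

    def test_yaml_round_trip(self, default_config_cached):
        text = default_config_cached.to_yaml()
        assert dfm.GeneratorConfig.from_yaml(text) == default_config_cached

    def test_yaml_file_round_trip(self, tmp_path, small_config):
        path = tmp_path / "config.yaml"
        small_config.to_yaml(path)
        assert dfm.GeneratorConfig.from_yaml(path) == small_config


class TestDeterminism:
    def test_same_config_same_seed_identical(self, small_config):
        a = dfm.generate_survey(small_config)
        b = dfm.generate_survey(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, small_config, small_survey):
        other = dfm.generate_survey(small_config, seed=small_config.seed + 1)
        assert not other.equals(small_survey)


class TestDegenerateSettings:
    def test_noise_free_flat_ladder(self):
        cfg = small_generator_config(
            ls_slope=0.0, ls_intercept=8.0, ls_noise_sd=1e-12, n_per_cell=50
        )
        data = dfm.generate_survey(cfg)
        assert (data["ls"] == 8).all()

    def test_saturated_thresholds_silence_all_items(self):
        cfg = small_generator_config(
            item_thresholds=((50.0, 51.0, 52.0, 53.0),) * 4, n_per_cell=50
        )
        data = dfm.generate_survey(cfg)
        for col in ITEM_COLUMNS:
            assert (data[col] == 5).all()
        assert (dfm.score_frame(data)["phc"] == 0).all()


class TestStructure:
    def test_cell_counts_and_weights(self, small_config, small_survey):
        counts = small_survey.groupby(["wave", "gender", "age_group"]).size()
        assert (counts == small_config.n_per_cell).all()
        means = small_survey.groupby("wave")["weight"].mean()
        assert np.allclose(means, 1.0)
        assert (small_survey["weight"] > 0).all()

    def test_clusters_nested_in_strata(self, small_survey):
        nesting = small_survey.groupby("cluster")["stratum"].nunique()
        assert (nesting == 1).all()

    def test_item_codes_and_ls_in_range(self, small_survey):
        for col in ITEM_COLUMNS:
            assert small_survey[col].isin([1, 2, 3, 4, 5]).all()
        assert small_survey["ls"].between(0, 10).all()


def _cluster_mc_se(cell_df, col):
    """Monte Carlo SE of a weighted cell mean from between-class variation."""
    totals = cell_df.groupby("cluster").apply(
        lambda g: np.average(g[col], weights=g["weight"]), include_groups=False
    )
    return totals.std(ddof=1) / np.sqrt(len(totals))


class TestAnalyticOracle:
    def test_empirical_phc_mean_within_3_se(self):
        cfg = small_generator_config(n_per_cell=4000, seed=99)
        scored = dfm.score_frame(dfm.generate_survey(cfg))
        for (w, g, a), cell_df in scored.groupby(["wave", "gender", "age_group"]):
            expected = dfm.expected_phc(cfg, (w, g, a))
            observed = np.average(cell_df["phc"], weights=cell_df["weight"])
            assert abs(observed - expected) < 3 * _cluster_mc_se(cell_df, "phc")

    def test_empirical_ls_mean_within_3_se(self):
        cfg = small_generator_config(n_per_cell=4000, seed=17)
        scored = dfm.score_frame(dfm.generate_survey(cfg))
        for (w, g, a), cell_df in scored.groupby(["wave", "gender", "age_group"]):
            expected = dfm.expected_ls(cfg, (w, g, a))
            observed = np.average(cell_df["ls_valid"], weights=cell_df["weight"])
            assert abs(observed - expected) < 3 * _cluster_mc_se(cell_df, "ls_valid")

    def test_raising_mu_monotone_in_both_outcomes(self, small_config):
        cell = ("2014", "girl", 13)
        grid = np.linspace(-2, 2, 9)
        phc = [dfm.expected_phc(small_config, cell, mu=m) for m in grid]
        cfgs = [
            dataclasses.replace(small_config, mu={**small_config.mu, cell: m})
            for m in grid
        ]
        ls = [dfm.expected_ls(c, cell) for c in cfgs]
        assert all(b > a for a, b in zip(phc, phc[1:]))
        assert all(b < a for a, b in zip(ls, ls[1:]))


def _anova_icc(scored):
    """One-way ANOVA intraclass correlation of the PHC score by class."""
    groups = [g["phc"].to_numpy() for _, g in scored.groupby("cluster")]
    sizes = np.array([len(g) for g in groups])
    grand = np.concatenate(groups).mean()
    msb = sum(n * (g.mean() - grand) ** 2 for n, g in zip(sizes, groups)) / (
        len(groups) - 1
    )
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (sizes.sum() - len(groups))
    n0 = (sizes.sum() - (sizes**2).sum() / sizes.sum()) / (len(groups) - 1)
    return (msb - msw) / (msb + (n0 - 1) * msw)


class TestClustering:
    def test_icc_positive_and_increasing_in_cluster_sd(self):
        iccs = []
        for sd in (0.1, 0.8):
            cfg = small_generator_config(cluster_sd=sd, n_per_cell=2500, seed=31)
            scored = dfm.score_frame(dfm.generate_survey(cfg))
            one_layer = scored[(scored.gender == "girl") & (scored.age_group == 13)]
            iccs.append(_anova_icc(one_layer))
        assert iccs[1] > iccs[0]
        assert iccs[1] > 0


class TestDefaultConfig:
    def test_documented_targets_carry_published_means(self):
        assert dfm.CALIBRATION_TARGETS[("2010", "girl", 15)] == (7.5, 6.9)
        assert dfm.CALIBRATION_TARGETS[("2014", "girl", 15)] == (8.6, 6.7)
        assert dfm.CALIBRATION_TARGETS[("2018", "girl", 15)] == (9.1, 6.9)
        assert dfm.CALIBRATION_TARGETS[("2010", "boy", 11)][0] == 5.1
        assert dfm.CALIBRATION_TARGETS[("2014", "boy", 11)][0] == 5.0
        assert dfm.CALIBRATION_TARGETS[("2018", "boy", 11)][0] == 5.9

    def test_calibration_inverts_expectations(self, default_config_cached):
        for cell, (phc_t, ls_t) in dfm.CALIBRATION_TARGETS.items():
            assert dfm.expected_phc(default_config_cached, cell) == pytest.approx(
                phc_t, abs=1e-6
            )
            assert dfm.expected_ls(default_config_cached, cell) == pytest.approx(
                ls_t, abs=1e-6
            )


class TestInjectMissingness:
    def test_zero_rates_identity(self, small_survey):
        out = dfm.inject_missingness(small_survey, 0.0, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, small_survey)

    def test_full_rates_blank_everything(self, small_survey):
        out = dfm.inject_missingness(small_survey, 1.0, 1.0, seed=1)
        for col in (*ITEM_COLUMNS, "ls"):
            assert out[col].isna().all()
        assert len(out) == len(small_survey)

    def test_rate_within_binomial_bound(self, small_survey):
        out = dfm.inject_missingness(small_survey, 0.1, 0.0, seed=5)
        n = len(out) * len(ITEM_COLUMNS)
        observed = sum(out[c].isna().sum() for c in ITEM_COLUMNS) / n
        bound = 3 * np.sqrt(0.1 * 0.9 / n)
        assert abs(observed - 0.1) < bound

    @pytest.mark.parametrize("rates", [(-0.1, 0.0), (0.0, 1.5)])
    def test_invalid_rates_rejected(self, small_survey, rates):
        with pytest.raises(dfm.ValidationError):
            dfm.inject_missingness(small_survey, *rates, seed=1)
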