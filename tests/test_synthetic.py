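"""Generator contracts: determinism, marginal distributions, exclusions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pagsem import (
    SyntheticConfig,
    apply_exclusions,
    generate_dataset,
    generate_measurement_dataset,
    sample_obesity,
    sample_weibull_indicator,
)
from pagsem.errors import ConfigError, DomainError


class TestConfigValidation:
    def test_invalid_fields_name_the_field(self):
        with pytest.raises(ConfigError, match="latent_corr"):
            SyntheticConfig(latent_corr=1.0)
        with pytest.raises(ConfigError, match="n_persons"):
            SyntheticConfig(n_persons=-1)
        with pytest.raises(ConfigError, match="weibull_shapes"):
            SyntheticConfig(weibull_shapes={"tv": -1})
        with pytest.raises(ConfigError, match="ethnicity"):
            SyntheticConfig(
                covariate_margins={
                    **SyntheticConfig().covariate_margins,
                    "ethnicity_probs": {"afro": 0.5, "indigenous": 0.2, "other": 0.2},
                }
            )

    def test_roundtrip_through_dict(self):
        cfg = SyntheticConfig(n_persons=50, seed=7, latent_corr=0.3)
        again = SyntheticConfig.from_dict(cfg.to_dict())
        assert again.to_dict() == cfg.to_dict()


class TestGenerateDataset:
    def test_deterministic_given_config_and_seed(self):
        cfg = SyntheticConfig(n_persons=500)
        a = generate_dataset(cfg, seed=42).data
        b = generate_dataset(cfg, seed=42).data
        pd.testing.assert_frame_equal(a, b)
        c = generate_dataset(cfg, seed=43).data
        assert not a["tv"].equals(c["tv"])

    def test_empty_dataset(self):
        ds = generate_dataset(SyntheticConfig(n_persons=0), seed=1)
        assert len(ds.data) == 0

    def test_obesity_flag_matches_bmi_threshold(self, small_dataset):
        df = small_dataset.data
        assert ((df["bmi"] >= 30) == (df["obesity"] == 1)).all()

    def test_prevalence_near_target_at_study_size(self):
        ds = generate_dataset(SyntheticConfig(n_persons=9658), seed=5)
        assert ds.data["obesity"].mean() == pytest.approx(0.191, abs=0.015)
        assert ds.meta["capped_fraction"] < 0.001

    def test_covariate_margins(self, small_dataset):
        df = small_dataset.data
        assert (df["sex"] == "female").mean() == pytest.approx(0.562, abs=0.03)
        assert df["age"].between(18, 64).all()
        assert (df["ethnicity"] == "afro").mean() == pytest.approx(0.071, abs=0.02)
        assert (df[["computer_smartphone", "tv", "videogames", "motor_vehicle",
                    "cycling", "walking"]] > 0).all().all()
        assert (df["expansion_factor"] > 0).all()

    def test_zero_loadings_and_paths_give_uncorrelated_log_times(self):
        cfg = SyntheticConfig(
            n_persons=10_000,
            loadings={j: 0.0 for j in SyntheticConfig().loadings},
            gamma_screens=0.0,
            gamma_transport=0.0,
            dept_transport_shift_sd=0.0,
        )
        df = generate_dataset(cfg, seed=9).data
        cols = ["computer_smartphone", "tv", "videogames", "motor_vehicle",
                "cycling", "walking"]
        R = np.corrcoef(np.log(df[cols].to_numpy()).T)
        off = R[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_latent_marginals_match_configured_moments(self):
        cfg = SyntheticConfig(n_persons=50_000, gamma_screens=0.0,
                              gamma_transport=0.0, dept_transport_shift_sd=0.0)
        df = generate_dataset(cfg, seed=11).data
        s1, s2 = cfg.latent_sds
        assert df["true_L1"].std() == pytest.approx(s1, rel=0.03)
        assert df["true_L2"].std() == pytest.approx(s2, rel=0.03)
        r = np.corrcoef(df["true_L1"], df["true_L2"])[0, 1]
        assert r == pytest.approx(cfg.latent_corr, abs=0.02)

    def test_indicator_marginally_weibull_when_latent_silent(self):
        """With zero loadings every indicator is exactly Weibull with the
        configured shape and scale (KS statistic < 0.01 at n = 50,000)."""
        cfg = SyntheticConfig(
            n_persons=50_000,
            loadings={j: 0.0 for j in SyntheticConfig().loadings},
            gamma_screens=0.0, gamma_transport=0.0, dept_transport_shift_sd=0.0,
        )
        df = generate_dataset(cfg, seed=13).data
        for j in ("tv", "cycling"):
            ks = stats.kstest(
                df[j],
                stats.weibull_min(
                    cfg.weibull_shapes[j],
                    scale=np.exp(cfg.indicator_intercepts[j]),
                ).cdf,
            ).statistic
            assert ks < 0.01


class TestSampleWeibullIndicator:
    def test_shape_one_is_exponential_with_mean_scale(self):
        rng = np.random.default_rng(0)
        t = sample_weibull_indicator(np.zeros(100_000), 0.0, np.log(420.0), 1.0, rng)
        assert t.mean() == pytest.approx(420.0, abs=5.0)

    def test_median_closed_form(self):
        rng = np.random.default_rng(1)
        t = sample_weibull_indicator(np.zeros(100_000), 0.0, np.log(100.0), 2.0, rng)
        assert np.median(t) == pytest.approx(100.0 * np.log(2.0) ** 0.5, abs=1.0)

    def test_zero_loading_independent_of_latent(self):
        rng = np.random.default_rng(2)
        L = np.linspace(-3, 3, 20_000)
        t = sample_weibull_indicator(L, 0.0, np.log(50.0), 1.3, rng)
        assert abs(np.corrcoef(L, np.log(t))[0, 1]) < 0.03

    def test_nonpositive_shape_rejected(self):
        with pytest.raises(DomainError):
            sample_weibull_indicator(np.zeros(3), 1.0, 0.0, 0.0, np.random.default_rng())


class TestSampleObesity:
    def test_extremes(self):
        rng = np.random.default_rng(3)
        flags, capped = sample_obesity(np.full(100, -np.inf), rng)
        assert not flags.any() and capped == 0.0
        flags, _ = sample_obesity(np.zeros(100), rng)
        assert flags.all()

    def test_rate_matches_probability(self):
        rng = np.random.default_rng(4)
        flags, capped = sample_obesity(np.full(100_000, np.log(0.2)), rng)
        assert flags.mean() == pytest.approx(0.2, abs=0.005)
        assert capped == 0.0

    def test_capped_fraction_reported_and_warned(self):
        rng = np.random.default_rng(5)
        with pytest.warns(RuntimeWarning):
            flags, capped = sample_obesity(np.full(100, 0.5), rng)
        assert capped == 1.0 and flags.all()


class TestApplyExclusions:
    def test_age_filter(self):
        df = pd.DataFrame({"age": [30] * 8 + [70, 70], "energy_kcal": 2000.0})
        kept, log = apply_exclusions(df)
        assert len(kept) == 8
        assert log["removed_age"] == 2

    def test_energy_percentiles_match_direct_oracle(self):
        rng = np.random.default_rng(6)
        energy = rng.lognormal(7.6, 0.4, size=1000)
        df = pd.DataFrame({"age": 40.0, "energy_kcal": energy})
        kept, log = apply_exclusions(df)
        lo, hi = np.percentile(energy, [1, 99])
        expected = int(((energy >= lo) & (energy <= hi)).sum())
        assert len(kept) == expected >= 980
        assert log["removed_energy"] == 1000 - expected

    def test_identity_when_nothing_excluded(self):
        df = pd.DataFrame({"age": np.linspace(20, 60, 50),
                           "energy_kcal": np.full(50, 2000.0)})
        kept, log = apply_exclusions(df)
        pd.testing.assert_frame_equal(kept, df)
        assert log["n_retained"] == 50

    def test_empty_input(self):
        kept, log = apply_exclusions(pd.DataFrame({"age": [], "energy_kcal": []}))
        assert len(kept) == 0 and log["n_retained"] == 0


def test_measurement_dataset_structure():
    df = generate_measurement_dataset("screens", 100, seed=3)
    assert list(df.columns) == ["computer_smartphone", "tv", "videogames", "true_L"]
    assert (df.drop(columns="true_L") > 0).all().all()
    with pytest.raises(DomainError):
        generate_measurement_dataset("nope", 10, seed=0)
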