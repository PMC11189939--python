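"""Generator tests: determinism, moment recovery, design structure."""

import numpy as np
import pandas as pd
import pytest

import thermopred as tp
from thermopred.simulate import GRADIENT_BOUNDS, standardized_occasion


class TestConfigValidation:
    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError, match="n_individuals"):
            tp.SimulationConfig(n_individuals=0)

    def test_prevalence_bounds(self):
        with pytest.raises(ValueError, match="prevalence"):
            tp.SimulationConfig(parasite_prevalence=1.2)

    def test_negative_sd_rejected(self):
        cov = dict(tp.simulate.DEFAULT_COVARIATES)
        cov["SVL_cm"] = (5.2, -1.0)
        with pytest.raises(ValueError, match="SVL_cm"):
            tp.SimulationConfig(covariate_means_sds=cov)

    def test_non_psd_correlation_rejected_with_name(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="correlation matrix"):
            tp.TrueParameters(corr=bad)

    def test_negative_random_effect_sd_rejected(self):
        with pytest.raises(ValueError, match="omega"):
            tp.TrueParameters(omega=-0.1)


class TestTraitTableGenerator:
    def test_identical_seed_identical_output(self, recovery_truth):
        cfg = tp.SimulationConfig(rng_seed=42)
        a = tp.simulate_trait_table(cfg, recovery_truth)
        b = tp.simulate_trait_table(cfg, recovery_truth)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_no_heterogeneity_is_iid_normal(self):
        """With all random-effect SDs zero and gamma0 = 0, responses are
        i.i.d. Normal(beta0, 1) and individuals are exchangeable."""
        truth = tp.TrueParameters(beta0=5.0)
        cfg = tp.SimulationConfig(n_individuals=600, rng_seed=1)
        df = tp.simulate_trait_table(cfg, truth, n_occasions=6)
        y = df["y"].to_numpy()
        assert abs(y.mean() - 5.0) < 0.06
        assert abs(y.std(ddof=1) - 1.0) < 0.03
        # between-individual variance of means is pure sampling noise 1/6
        v_means = df.groupby("individual_id")["y"].mean().var(ddof=1)
        assert abs(v_means - 1.0 / 6.0) < 0.05

    def test_moment_recovery_between_variance_and_residual_scale(self):
        """Large-simulation moment oracle: the empirical between-individual
        variance matches sd_intercept^2 and the pooled residual SD matches
        exp(gamma0), within Monte-Carlo error."""
        truth = tp.TrueParameters(sd_intercept=0.68, gamma0=-0.48)
        cfg = tp.SimulationConfig(n_individuals=10_000, rng_seed=2)
        df = tp.simulate_trait_table(cfg, truth, n_occasions=6)
        by_ind = df.groupby("individual_id")["y"]
        resid_var = by_ind.var(ddof=1).mean()
        between = by_ind.mean().var(ddof=1) - resid_var / 6.0
        assert abs(between - 0.68**2) < 0.03  # ~3 MC standard errors
        assert abs(np.sqrt(resid_var) - np.exp(-0.48)) < 0.01

    def test_dispersion_random_effect_spreads_residual_sds(self):
        truth = tp.TrueParameters(omega=0.5, gamma0=0.0)
        cfg = tp.SimulationConfig(n_individuals=4000, rng_seed=3)
        df = tp.simulate_trait_table(cfg, truth, n_occasions=50)
        log_sd = np.log(df.groupby("individual_id")["y"].std(ddof=1))
        assert abs(log_sd.std(ddof=1) - 0.5) < 0.05

    def test_unknown_covariate_name_rejected(self):
        truth = tp.TrueParameters(beta={"no_such_column": 1.0})
        with pytest.raises(KeyError, match="no_such_column"):
            tp.simulate_trait_table(tp.SimulationConfig(), truth)

    def test_time_covariate_is_zscored_occasion_index(self):
        t = standardized_occasion(6)
        assert abs(t.mean()) < 1e-12
        assert abs(t.std(ddof=1) - 1.0) < 1e-12
        assert np.all(np.diff(t) > 0)


class TestRawGenerator:
    def test_too_few_readings_rejected(self):
        with pytest.raises(ValueError, match="readings_per_day"):
            tp.simulate_raw_dataset(tp.SimulationConfig(readings_per_day=3))

    def test_log_schema_and_bounds(self):
        raw = tp.simulate_raw_dataset(tp.SimulationConfig(rng_seed=4))
        lo, hi = GRADIENT_BOUNDS
        assert raw.thermal_log["body_temp_C"].between(lo, hi).all()
        assert len(raw.thermal_log) == 36 * 6 * 22
        beh = raw.behaviour_log
        assert len(beh) == 36 * 5
        assert beh["sheltering_s"].between(0, 3600).all()
        assert beh["time_outside_s"].between(0, 3600).all()
        assert (beh["transitions"] >= 0).all()
        assert (beh["transitions"] == beh["transitions"].astype(int)).all()
        assert (beh["risk_latency_s"] >= 0).all()
        # every (individual, day) pair present exactly once
        assert not beh.duplicated(["individual_id", "day_index"]).any()

    def test_determinism(self):
        a = tp.simulate_raw_dataset(tp.SimulationConfig(rng_seed=5))
        b = tp.simulate_raw_dataset(tp.SimulationConfig(rng_seed=5))
        pd.testing.assert_frame_equal(a.thermal_log, b.thermal_log)
        pd.testing.assert_frame_equal(a.behaviour_log, b.behaviour_log)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_homogeneous_truth_gives_exchangeable_days(self):
        """With no heterogeneity, all individual-day summary statistics
        differ only by within-day sampling noise."""
        truth = tp.study_truth()
        truth["T_sel"] = tp.TrueParameters(beta0=32.0)
        truth["T_set"] = tp.TrueParameters(beta0=4.0)
        raw = tp.simulate_raw_dataset(tp.SimulationConfig(rng_seed=6), truth)
        med = raw.thermal_log.groupby(["individual_id", "day_index"])["body_temp_C"].median()
        # spread of day medians ~ 1.25 * sigma_day / sqrt(22), sigma_day = 4/1.349
        assert med.std(ddof=1) < 3 * 1.25 * (4.0 / 1.349) / np.sqrt(22)

    def test_clamping_warning_when_spread_exceeds_gradient(self):
        truth = tp.study_truth()
        truth["T_set"] = tp.TrueParameters(beta0=40.0)  # absurd within-day spread
        with pytest.warns(UserWarning, match="clamping"):
            tp.simulate_raw_dataset(tp.SimulationConfig(rng_seed=7), truth)

    def test_parasite_prevalence_and_intensity(self):
        cfg = tp.SimulationConfig(n_individuals=4000, rng_seed=8)
        cov = tp.simulate_covariates(cfg)
        counts = cov[["parasite_count_1", "parasite_count_2", "parasite_count_3"]]
        infected = (counts.sum(axis=1) > 0).mean()
        assert abs(infected - 0.806) < 0.03
        assert abs(counts.mean(axis=1).mean() - 4.75) < 0.35


class TestMultiTraitGenerator:
    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            tp.simulate_multitrait_table(
                tp.SimulationConfig(), np.eye(4), np.eye(4),
                trait_names=("a", "b", "c"),
            )

    def test_non_psd_covariance_rejected_by_name(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="sigma_between"):
            tp.simulate_multitrait_table(
                tp.SimulationConfig(), bad, np.eye(2), trait_names=("a", "b")
            )

    def test_zero_between_covariance_gives_null_correlations(self):
        """Sigma_B = 0: correlations of individual means stay below
        Monte-Carlo error at 500 individuals."""
        cfg = tp.SimulationConfig(n_individuals=500, rng_seed=9)
        names = ("a", "b", "c")
        df = tp.simulate_multitrait_table(
            cfg, np.zeros((3, 3)), np.eye(3), trait_names=names, n_occasions=8
        )
        r = df.groupby("individual_id")[list(names)].mean().corr().to_numpy()
        off = r[np.triu_indices(3, 1)]
        assert np.abs(off).max() < 3.5 / np.sqrt(500)

    def test_two_trait_between_correlation_moment_oracle(self):
        """r_B = 0.8 with Sigma_W = 0: the correlation of individual means
        recovers 0.8 within Monte-Carlo error."""
        cfg = tp.SimulationConfig(n_individuals=500, rng_seed=10)
        sb = np.array([[1.0, 0.8], [0.8, 1.0]])
        df = tp.simulate_multitrait_table(
            cfg, sb, np.zeros((2, 2)), trait_names=("a", "b"), n_occasions=4
        )
        r = df.groupby("individual_id")[["a", "b"]].mean().corr().iloc[0, 1]
        assert abs(r - 0.8) < 0.05

    def test_missing_by_design_blocks_never_cooccur(self):
        cfg = tp.SimulationConfig(rng_seed=11)
        df = tp.simulate_multitrait_table(
            cfg, *tp.study_syndrome_covariances(), missing_by_design=True
        )
        thermal = df[list(tp.simulate.THERMAL_TRAITS)].notna().any(axis=1)
        behaviour = df[list(tp.simulate.BEHAVIOUR_TRAITS)].notna().any(axis=1)
        assert not (thermal & behaviour).any()
        one = df[df["individual_id"] == 1]
        assert thermal[one.index].sum() == 6
        assert behaviour[one.index].sum() == 5

    def test_syndrome_preset_is_psd_with_reported_sign_pattern(self):
        sb, sw = tp.study_syndrome_covariances()
        assert np.linalg.eigvalsh(sb).min() > 0
        d = np.sqrt(np.diag(sb))
        r = sb / np.outer(d, d)
        assert r[3, 4] < -0.4  # activity-sheltering strongly negative
        assert r[4, 5] > 0.4   # sheltering-risk-taking positive
        assert r[0, 2] > 0.2   # T_sel-T_Vmax positive
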