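"""Location–scale model tests: likelihood, gradient, sampler, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thermopred as tp
from thermopred.dhmm import (
    DHMMSpec,
    _Posterior,
    _prepare_data,
    dhmm_loglik,
    diagnose,
    hpd_interval,
)


def _random_dataset(rng, n_ind=4, n_occ=5):
    rows = []
    t = np.linspace(-1, 1, n_occ)
    for i in range(n_ind):
        for j in range(n_occ):
            rows.append(
                {"individual_id": i + 1, "time": t[j], "x": rng.normal(),
                 "y": rng.normal()}
            )
    return pd.DataFrame(rows)


def _random_params(rng, spec, n_ind):
    return {
        "beta0": rng.normal(),
        "beta": {term: rng.normal() for term in spec.mean_terms},
        "gamma0": 0.3 * rng.normal(),
        "gamma": {term: 0.3 * rng.normal() for term in spec.residual_terms},
        "a": rng.normal(size=n_ind),
        "b": rng.normal(size=n_ind),
        "w": 0.3 * rng.normal(size=n_ind),
    }


class TestLoglik:
    def test_standard_normal_mode(self):
        """A single observation equal to the linear predictor with unit
        residual SD contributes exactly -log(2*pi)/2."""
        df = pd.DataFrame({"individual_id": [1], "time": [0.0], "y": [1.7]})
        spec = DHMMSpec(response="y", mean_terms=())
        val = dhmm_loglik(spec, {"beta0": 1.7, "gamma0": 0.0, "a": [0.0], "b": [0.0], "w": [0.0]}, df)
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_matches_term_by_term_bruteforce(self):
        """Equals the sum of independently evaluated normal log-densities."""
        rng = np.random.default_rng(3)
        df = _random_dataset(rng)
        spec = DHMMSpec(response="y", mean_terms=("time", "x"), residual_terms=("x",))
        params = _random_params(rng, spec, 4)
        expected = 0.0
        for row in df.itertuples():
            i = row.individual_id - 1
            mu = (params["beta0"] + params["beta"]["time"] * row.time
                  + params["beta"]["x"] * row.x
                  + params["a"][i] + params["b"][i] * row.time)
            sigma = np.exp(params["gamma0"] + params["gamma"]["x"] * row.x + params["w"][i])
            expected += stats.norm.logpdf(row.y, mu, sigma)
        assert dhmm_loglik(spec, params, df) == pytest.approx(expected, abs=1e-10)

    def test_gaussian_sign_symmetry(self):
        rng = np.random.default_rng(4)
        df = _random_dataset(rng)
        spec = DHMMSpec(response="y", mean_terms=("time",))
        params = _random_params(rng, spec, 4)
        base = dhmm_loglik(spec, params, df)
        flipped = dict(params)
        flipped["beta0"] = -params["beta0"]
        flipped["beta"] = {k: -v for k, v in params["beta"].items()}
        flipped["a"] = -np.asarray(params["a"])
        flipped["b"] = -np.asarray(params["b"])
        neg = df.assign(y=-df["y"])
        assert dhmm_loglik(spec, flipped, neg) == pytest.approx(base, abs=1e-10)

    def test_nonfinite_parameter_propagates(self):
        df = _random_dataset(np.random.default_rng(5))
        spec = DHMMSpec(response="y")
        val = dhmm_loglik(
            spec, {"beta0": np.nan, "gamma0": 0.0, "a": np.zeros(4), "b": np.zeros(4), "w": np.zeros(4)}, df
        )
        assert not np.isfinite(val)

    def test_individual_label_permutation_invariance(self):
        rng = np.random.default_rng(6)
        df = _random_dataset(rng)
        spec = DHMMSpec(response="y", mean_terms=("time",))
        params = _random_params(rng, spec, 4)
        base = dhmm_loglik(spec, params, df)
        # relabel 1..4 -> 4..1; effect arrays follow the sorted-label order
        relabeled = df.assign(individual_id=5 - df["individual_id"])
        permuted = dict(params)
        for key in ("a", "b", "w"):
            permuted[key] = np.asarray(params[key])[::-1]
        assert dhmm_loglik(spec, permuted, relabeled) == pytest.approx(base, abs=1e-9)

    def test_residual_model_refuses_time(self):
        with pytest.raises(ValueError, match="time"):
            DHMMSpec(response="y", residual_terms=("time",))


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        df = _random_dataset(rng, n_ind=6, n_occ=4)
        md = _prepare_data(DHMMSpec(response="y", mean_terms=("time", "x"), residual_terms=("x",)), df)
        post = _Posterior(md)
        theta = 0.3 * rng.standard_normal(post.dim)
        _, grad = post.logpost_grad(theta)
        eps = 1e-6
        for i in range(post.dim):
            up, dn = theta.copy(), theta.copy()
            up[i] += eps
            dn[i] -= eps
            num = (post.logpost_grad(up)[0] - post.logpost_grad(dn)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestSampler:
    def test_determinism_under_fixed_seed(self, recovery_truth):
        cfg = tp.SimulationConfig(n_individuals=8, rng_seed=8)
        df = tp.simulate_trait_table(cfg, recovery_truth, n_occasions=4)
        kw = dict(chains=2, iterations=300, warmup=150, thin=1, seed=5)
        a = tp.sample_dhmm(DHMMSpec.minimal("y"), df, **kw)
        b = tp.sample_dhmm(DHMMSpec.minimal("y"), df, **kw)
        for name in a.params:
            assert np.array_equal(a.params[name], b.params[name])

    def test_insufficient_data_rejected(self, recovery_truth):
        cfg = tp.SimulationConfig(n_individuals=1, rng_seed=9)
        df = tp.simulate_trait_table(cfg, recovery_truth, n_occasions=6)
        with pytest.raises(ValueError, match="2 individuals"):
            tp.sample_dhmm(DHMMSpec.minimal("y"), df)

    def test_prior_recovery_without_data(self, recovery_truth):
        """With the likelihood switched off the sampler reproduces the
        priors: half-Normal(0,1) moments for the SDs, Normal(0,1) for the
        intercept, near-uniform correlations."""
        cfg = tp.SimulationConfig(n_individuals=4, rng_seed=10)
        df = tp.simulate_trait_table(cfg, recovery_truth, n_occasions=3)
        post = tp.sample_dhmm(
            DHMMSpec.minimal("y"), df, chains=4, iterations=2000, warmup=500,
            thin=1, seed=6, prior_only=True,
        )
        half_normal_mean = np.sqrt(2 / np.pi)
        for name in ("sd_intercept", "sd_time", "omega"):
            assert post.stacked(name).mean() == pytest.approx(half_normal_mean, abs=0.06)
        assert post.stacked("beta0").std() == pytest.approx(1.0, abs=0.08)
        assert abs(post.stacked("r_intercept_omega").mean()) < 0.08

    def test_posterior_draw_invariants(self, study_scale_fit):
        _, post = study_scale_fit
        assert post.n_chains == 4
        assert post.n_draws == 1000
        for name in ("sd_intercept", "sd_time", "omega"):
            assert (post.stacked(name) >= 0).all()
        for name in ("r_intercept_slope", "r_intercept_omega", "r_slope_omega"):
            r = post.stacked(name)
            assert (np.abs(r) <= 1).all()

    def test_recovery_at_study_scale(self, study_scale_fit, recovery_truth):
        """95% HPD intervals bracket the generating values on one
        study-sized dataset."""
        _, post = study_scale_fit
        truth = {
            "sd_intercept": recovery_truth.sd_intercept,
            "omega": recovery_truth.omega,
            "gamma0": recovery_truth.gamma0,
            "r_intercept_omega": recovery_truth.corr[0, 2],
        }
        for name, val in truth.items():
            lo, hi = hpd_interval(post.stacked(name))
            assert lo - 0.05 <= val <= hi + 0.05, (name, val, lo, hi)

    def test_serialized_draws_round_trip(self, study_scale_fit):
        _, post = study_scale_fit
        df = post.to_dataframe()
        assert len(df) == post.n_chains * post.n_draws
        assert {"chain", "iteration", "sd_intercept", "omega"} <= set(df.columns)
        # per-draw correlation matrix of (a, b, w) stays a correlation
        assert df["r_intercept_slope"].between(-1, 1).all()


class TestDiagnostics:
    def test_iid_chains_pass(self):
        rng = np.random.default_rng(11)
        params = {"p": rng.standard_normal((4, 500))}
        report = diagnose(params)
        assert report.passed
        assert report.table["ess"].iloc[0] > 1000

    def test_disagreeing_chains_flagged(self):
        rng = np.random.default_rng(12)
        draws = rng.standard_normal((2, 500))
        draws[1] += 3.0
        report = diagnose({"p": draws})
        assert not report.passed
        assert report.table["rhat"].iloc[0] > 1.2
        assert "FAIL" in str(report)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            diagnose({"p": np.random.default_rng(13).standard_normal((1, 500))})

    def test_short_chains_rejected(self):
        with pytest.raises(ValueError, match="100 kept draws"):
            diagnose({"p": np.random.default_rng(14).standard_normal((4, 50))})


class TestHPD:
    def test_uniform_grid(self):
        draws = np.linspace(0.0, 1.0, 1000)
        lo, hi = hpd_interval(draws, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_skewed_draws_match_exhaustive_scan(self):
        rng = np.random.default_rng(15)
        draws = rng.lognormal(0.0, 0.8, size=1000)
        lo, hi = hpd_interval(draws, 0.95)
        xs = np.sort(draws)
        m = int(np.ceil(0.95 * len(xs)))
        best = min(
            ((xs[k + m - 1] - xs[k], xs[k], xs[k + m - 1]) for k in range(len(xs) - m + 1)),
            key=lambda t: t[0],
        )
        assert (lo, hi) == (best[1], best[2])
        # skew pulls the HPD below the equal-tail interval
        assert hi < np.quantile(draws, 0.975)

    def test_symmetric_draws_match_equal_tail(self):
        rng = np.random.default_rng(16)
        draws = rng.standard_normal(20_000)
        lo, hi = hpd_interval(draws, 0.95)
        assert lo == pytest.approx(np.quantile(draws, 0.025), abs=0.05)
        assert hi == pytest.approx(np.quantile(draws, 0.975), abs=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="100 draws"):
            hpd_interval(np.arange(50))
        with pytest.raises(ValueError, match="mass"):
            hpd_interval(np.arange(200), mass=1.5)
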