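"""Double-hierarchical Gaussian model: specification, likelihood, MCMC, diagnostics.

The model pairs a *mean* submodel and a *residual* (dispersion) submodel.
For individual i on occasion j,

    y_ij ~ Normal(mu_ij, sigma_ij)
    mu_ij        = beta0 + x_ij' beta + a_i + b_i t_j
    log sigma_ij = gamma0 + x_ij' gamma + w_i

with (a_i, b_i, w_i) ~ MVN(0, diag(s) R diag(s)), s = (sd_intercept,
sd_time, omega).  ``a`` is the behavioural type, ``b`` the individual
habituation slope, and ``w`` the individual log-residual-SD offset whose SD
omega quantifies heterogeneity in predictability.  Time enters the mean
submodel only, as both a fixed effect and the random slope; the residual
submodel carries the state covariates but no time term.

Priors follow the analysis convention: Normal(0, 1) on fixed effects,
half-Normal(0, 1) on the three random-effect SDs, LKJ(1) on R.  Sampling
is Hamiltonian Monte Carlo on the unconstrained scale — non-centred random
effects, log SDs, and the tanh / canonical-partial-correlation
parameterisation of the Cholesky factor of R — with dual-averaging step
size and diagonal mass adaptation during warmup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))

#: convergence thresholds: split-chain R-hat and effective sample size
RHAT_THRESHOLD = 1.01
ESS_THRESHOLD = 400.0

#: MCMC length presets; "paper" reproduces 4 x (5000 - 1000) / 4 = 4000 kept
#: draws, "desk" keeps the same draw count from shorter unthinned chains
MCMC_PRESETS: dict[str, dict[str, int]] = {
    "paper": {"chains": 4, "iterations": 5000, "warmup": 1000, "thin": 4},
    "desk": {"chains": 4, "iterations": 1500, "warmup": 500, "thin": 1},
}

#: Beta(b, b) exponents of the three canonical partial correlations under
#: LKJ(1) in dimension 3, order (a-b, a-w, b-w)
_LKJ_BETA = np.array([1.5, 1.0, 1.5])

STUDY_COVARIATES = (
    "SVL_z",
    "relative_head_size_z",
    "condition_z",
    "parasite_intensity_z",
    "parasite_intensity_z:SVL_z",
    "parasite_intensity_z:relative_head_size_z",
    "parasite_intensity_z:condition_z",
)


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DHMMSpec:
    """Names the response and the fixed-effect terms of both submodels.

    ``mean_terms`` may include ``time`` (habituation fixed effect) and
    interaction terms written ``"colA:colB"``; ``residual_terms`` must not
    include time.  The random-effect structure is fixed by the model:
    individual intercept and time slope in the mean submodel, individual
    intercept in the residual submodel, fully correlated.
    """

    response: str
    mean_terms: tuple[str, ...] = ("time",)
    residual_terms: tuple[str, ...] = ()
    individual: str = "individual_id"
    time: str = "time"

    def __post_init__(self):
        if self.time in self.residual_terms:
            raise ValueError(
                "the residual submodel must not contain the time fixed effect"
            )

    @classmethod
    def study_default(cls, response: str) -> "DHMMSpec":
        """Full state-covariate specification: time (mean model only), SVL,
        relative head size, condition, parasite load and the three
        parasite x size interactions in both submodels."""
        return cls(
            response=response,
            mean_terms=("time",) + STUDY_COVARIATES,
            residual_terms=STUDY_COVARIATES,
        )

    @classmethod
    def minimal(cls, response: str) -> "DHMMSpec":
        """Intercept + time mean model, intercept-only residual model."""
        return cls(response=response)


def _design_matrix(df: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for term in terms:
        parts = term.split(":")
        v = np.ones(len(df))
        for p in parts:
            if p not in df.columns:
                raise KeyError(f"model term {p!r} not found in the trait table")
            v = v * df[p].to_numpy(dtype=float)
        cols.append(v)
    return np.column_stack(cols)


@dataclass
class _ModelData:
    y: np.ndarray
    x_mean: np.ndarray
    x_res: np.ndarray
    t: np.ndarray
    idx: np.ndarray
    individuals: np.ndarray  # sorted original labels
    n_dropped: int


def _prepare_data(spec: DHMMSpec, df: pd.DataFrame) -> _ModelData:
    needed = {spec.response, spec.individual, spec.time}
    for term in spec.mean_terms + spec.residual_terms:
        needed.update(term.split(":"))
    missing_cols = needed - set(df.columns)
    if missing_cols:
        raise KeyError(f"trait table lacks columns: {sorted(missing_cols)}")
    sub = df[sorted(needed)].copy()
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "dropping %d rows with missing %s or covariates", n_dropped, spec.response
        )
    sub = sub[complete]
    # canonical internal order: by individual label, then time
    sub = sub.sort_values([spec.individual, spec.time], kind="mergesort")
    individuals, idx = np.unique(sub[spec.individual].to_numpy(), return_inverse=True)
    return _ModelData(
        y=sub[spec.response].to_numpy(dtype=float),
        x_mean=_design_matrix(sub, spec.mean_terms),
        x_res=_design_matrix(sub, spec.residual_terms),
        t=sub[spec.time].to_numpy(dtype=float),
        idx=idx,
        individuals=individuals,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def dhmm_loglik(spec: DHMMSpec, params: dict, data: pd.DataFrame) -> float:
    """Exact Gaussian log-likelihood of the location–scale model.

    ``params`` holds ``beta0``, ``gamma0``, coefficient dicts ``beta`` /
    ``gamma`` keyed by term name, and per-individual effect arrays ``a``,
    ``b``, ``w`` aligned with the sorted individual labels.  Non-finite
    parameters yield a non-finite value, never a silently clipped one.
    """
    md = _prepare_data(spec, data)
    n_ind = len(md.individuals)

    def _coef_vector(intercept, coefs, terms):
        v = np.empty(len(terms) + 1)
        v[0] = intercept
        for k, term in enumerate(terms):
            v[k + 1] = coefs.get(term, 0.0)
        return v

    beta = _coef_vector(params["beta0"], params.get("beta", {}), spec.mean_terms)
    gamma = _coef_vector(params["gamma0"], params.get("gamma", {}), spec.residual_terms)
    a = np.asarray(params.get("a", np.zeros(n_ind)), dtype=float)
    b = np.asarray(params.get("b", np.zeros(n_ind)), dtype=float)
    w = np.asarray(params.get("w", np.zeros(n_ind)), dtype=float)
    if not (len(a) == len(b) == len(w) == n_ind):
        raise ValueError(
            f"random-effect arrays must have length {n_ind} (one per individual)"
        )

    mu = md.x_mean @ beta + a[md.idx] + b[md.idx] * md.t
    log_sigma = md.x_res @ gamma + w[md.idx]
    with np.errstate(over="ignore", invalid="ignore"):
        z = (md.y - mu) * np.exp(-log_sigma)
        return float(-0.5 * np.sum(z * z) - np.sum(log_sigma) - 0.5 * len(md.y) * _LOG_2PI)


# ---------------------------------------------------------------------------
# unconstrained log posterior and gradient
# ---------------------------------------------------------------------------

def _chol_from_cpc(w: np.ndarray) -> np.ndarray:
    """Cholesky factor of the 3x3 correlation from canonical partial
    correlations w = (w_ab, w_aw, w_bw), each in (-1, 1)."""
    w0, w1, w2 = w
    L = np.zeros((3, 3))
    L[0, 0] = 1.0
    L[1, 0] = w0
    L[1, 1] = np.sqrt(1.0 - w0 * w0)
    L[2, 0] = w1
    q = np.sqrt(1.0 - w1 * w1)
    L[2, 1] = w2 * q
    L[2, 2] = q * np.sqrt(1.0 - w2 * w2)
    return L


class _Posterior:
    """Unconstrained-scale log posterior with analytic gradient.

    Parameter vector layout: [beta (pm), gamma (pr), eta = log SDs (3),
    c = atanh CPCs (3), z latent effects (I*3, row-major)].
    """

    def __init__(self, md: _ModelData, likelihood: bool = True):
        self.md = md
        self.likelihood = likelihood
        self.pm = md.x_mean.shape[1]
        self.pr = md.x_res.shape[1]
        self.n_ind = len(md.individuals)
        self.dim = self.pm + self.pr + 6 + 3 * self.n_ind

    def unpack(self, theta: np.ndarray):
        pm, pr, ni = self.pm, self.pr, self.n_ind
        beta = theta[:pm]
        gamma = theta[pm : pm + pr]
        eta = theta[pm + pr : pm + pr + 3]
        c = theta[pm + pr + 3 : pm + pr + 6]
        z = theta[pm + pr + 6 :].reshape(ni, 3)
        return beta, gamma, eta, c, z

    def logpost_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        md = self.md
        beta, gamma, eta, c, z = self.unpack(theta)
        if np.any(np.abs(eta) > 20) or np.any(np.abs(c) > 8):
            # tanh(c) indistinguishable from +-1 beyond this: reject early
            return -np.inf, np.zeros_like(theta)

        s = np.exp(eta)
        wc = np.tanh(c)
        L = _chol_from_cpc(wc)
        M = s[:, None] * L  # diag(s) @ L
        r = z @ M.T  # (I, 3): columns a, b, w

        grad = np.zeros_like(theta)
        pm, pr = self.pm, self.pr
        g_beta = grad[:pm]
        g_gamma = grad[pm : pm + pr]

        # priors: N(0,1) fixed effects, N(0,1) latent, half-N(0,1) SDs with
        # log-transform Jacobian, LKJ(1) on the CPCs with tanh Jacobian
        lp = -0.5 * float(beta @ beta) - 0.5 * float(gamma @ gamma)
        lp += -0.5 * float((z * z).sum())
        lp += float(np.sum(-0.5 * s * s + eta))
        lp += float(np.sum(_LKJ_BETA * np.log1p(-wc * wc)))
        g_beta -= beta
        g_gamma -= gamma
        g_eta = -s * s + 1.0
        g_c = -2.0 * _LKJ_BETA * wc
        g_z = -z

        if self.likelihood:
            mu = md.x_mean @ beta + r[md.idx, 0] + r[md.idx, 1] * md.t
            ls = md.x_res @ gamma + r[md.idx, 2]
            if np.any(np.abs(ls) > 40):
                return -np.inf, np.zeros_like(theta)
            inv_sig = np.exp(-ls)
            e = (md.y - mu) * inv_sig
            lp += -0.5 * float(e @ e) - float(ls.sum()) - 0.5 * len(md.y) * _LOG_2PI

            d_mu = e * inv_sig  # d loglik / d mu
            g_ls = e * e - 1.0  # d loglik / d log sigma
            g_beta += md.x_mean.T @ d_mu
            g_gamma += md.x_res.T @ g_ls
            ni = self.n_ind
            G = np.column_stack(
                [
                    np.bincount(md.idx, weights=d_mu, minlength=ni),
                    np.bincount(md.idx, weights=d_mu * md.t, minlength=ni),
                    np.bincount(md.idx, weights=g_ls, minlength=ni),
                ]
            )
            g_z += G @ M
            A = G.T @ z  # d loglik / d M
            g_eta += s * (A * L).sum(axis=1)
            dL = s[:, None] * A
            w0, w1, w2 = wc
            q = np.sqrt(1.0 - w1 * w1)
            s2 = np.sqrt(1.0 - w2 * w2)
            g_w = np.array(
                [
                    dL[1, 0] + dL[1, 1] * (-w0 / np.sqrt(1.0 - w0 * w0)),
                    dL[2, 0] + (dL[2, 1] * w2 + dL[2, 2] * s2) * (-w1 / q),
                    dL[2, 1] * q + dL[2, 2] * q * (-w2 / s2),
                ]
            )
            g_c += g_w * (1.0 - wc * wc)

        grad[pm + pr : pm + pr + 3] = g_eta
        grad[pm + pr + 3 : pm + pr + 6] = g_c
        grad[pm + pr + 6 :] = g_z.ravel()
        if not np.isfinite(lp):
            return -np.inf, np.zeros_like(theta)
        return lp, grad


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ---------------------------------------------------------------------------

def _hmc_chain(
    post: _Posterior,
    theta0: np.ndarray,
    *,
    iterations: int,
    warmup: int,
    thin: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_leapfrog: int = 32,
) -> tuple[np.ndarray, float]:
    """One HMC chain; returns kept draws (n_kept, dim) and acceptance rate."""
    theta = theta0.copy()
    lp, grad = post.logpost_grad(theta)
    if not np.isfinite(lp):
        raise RuntimeError("non-finite log posterior at the chain's initial value")

    inv_mass = np.ones(post.dim)
    sqrt_mass = np.ones(post.dim)
    step = 0.1
    # dual averaging (Hoffman & Gelman): gamma=0.05, t0=10, kappa=0.75
    mu_da = np.log(10.0 * step)
    h_bar, log_step_bar, da_iter = 0.0, 0.0, 0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75

    # warmup phases: [0, w1) step only; [w1, w2) step + variance collection;
    # at w2 swap in the diagonal mass and restart dual averaging
    w1 = max(int(0.15 * warmup), 1)
    w2 = max(int(0.8 * warmup), w1 + 1)
    var_sum = np.zeros(post.dim)
    var_sumsq = np.zeros(post.dim)
    var_n = 0

    kept = []
    n_accept = 0
    n_total = 0
    for it in range(iterations):
        adapting = it < warmup
        p = rng.standard_normal(post.dim) * sqrt_mass
        h0 = -lp + 0.5 * float(p * p @ inv_mass)
        theta_new, grad_new = theta, grad
        p_half = p + 0.5 * step * grad
        n_leap = int(rng.integers(1, max_leapfrog + 1))
        diverged = False
        for leap in range(n_leap):
            theta_new = theta_new + step * (inv_mass * p_half)
            lp_new, grad_new = post.logpost_grad(theta_new)
            if not np.isfinite(lp_new):
                diverged = True
                break
            if leap < n_leap - 1:
                p_half = p_half + step * grad_new
        if diverged:
            accept_prob = 0.0
        else:
            p_new = p_half + 0.5 * step * grad_new
            h1 = -lp_new + 0.5 * float(p_new * p_new @ inv_mass)
            accept_prob = min(1.0, float(np.exp(min(h0 - h1, 0.0))))
            if rng.random() < accept_prob:
                theta, lp, grad = theta_new, lp_new, grad_new
        if not adapting:
            n_total += 1
            n_accept += accept_prob
        if adapting:
            da_iter += 1
            h_bar = (1.0 - 1.0 / (da_iter + t0_da)) * h_bar + (
                target_accept - accept_prob
            ) / (da_iter + t0_da)
            log_step = mu_da - np.sqrt(da_iter) / gamma_da * h_bar
            eta_da = da_iter ** (-kappa_da)
            log_step_bar = eta_da * log_step + (1.0 - eta_da) * log_step_bar
            step = float(np.exp(log_step))
            if w1 <= it < w2:
                var_sum += theta
                var_sumsq += theta * theta
                var_n += 1
            if it == w2 - 1 and var_n > 10:
                var = var_sumsq / var_n - (var_sum / var_n) ** 2
                var = np.clip(var, 1e-6, None)
                # regularize toward unit scale (as in windowed adaptation)
                var = (var_n * var + 5.0) / (var_n + 5.0)
                inv_mass = var
                sqrt_mass = 1.0 / np.sqrt(var)
                mu_da = np.log(10.0 * step)
                h_bar, log_step_bar, da_iter = 0.0, 0.0, 0
            if it == warmup - 1:
                step = float(np.exp(log_step_bar))
        elif (it - warmup + 1) % thin == 0:
            kept.append(theta.copy())
    accept_rate = float(n_accept / max(n_total, 1))
    return np.asarray(kept), accept_rate


# ---------------------------------------------------------------------------
# posterior container, sampling front-end
# ---------------------------------------------------------------------------

POPULATION_PARAMS = (
    "sd_intercept",
    "sd_time",
    "omega",
    "r_intercept_slope",
    "r_intercept_omega",
    "r_slope_omega",
)


@dataclass
class DHMMPosterior:
    """Posterior draws of every model parameter, shape (chains, draws)."""

    spec: DHMMSpec
    params: dict[str, np.ndarray]
    random_effects: np.ndarray  # (chains, draws, individuals, 3) for (a, b, w)
    individuals: np.ndarray
    accept_rates: tuple[float, ...]
    n_dropped_rows: int = 0

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All draws of one parameter, chains concatenated."""
        return self.params[name].reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.stacked(name).mean())

    def to_dataframe(self) -> pd.DataFrame:
        """One row per draw with chain and iteration columns, auditable
        from any environment."""
        nc, nd = self.n_chains, self.n_draws
        out = {
            "chain": np.repeat(np.arange(1, nc + 1), nd),
            "iteration": np.tile(np.arange(1, nd + 1), nc),
        }
        for name, arr in self.params.items():
            out[name] = arr.reshape(-1)
        for k, ind in enumerate(self.individuals):
            for j, eff in enumerate(("a", "b", "w")):
                out[f"{eff}[{ind}]"] = self.random_effects[:, :, k, j].reshape(-1)
        return pd.DataFrame(out)


def _initial_theta(post: _Posterior, rng: np.random.Generator) -> np.ndarray:
    theta = 0.1 * rng.standard_normal(post.dim)
    pm, pr = post.pm, post.pr
    theta[pm + pr : pm + pr + 3] = np.log(0.5) + 0.2 * rng.standard_normal(3)
    return theta


def sample_dhmm(
    spec: DHMMSpec,
    data: pd.DataFrame,
    *,
    chains: int = 4,
    iterations: int = 5000,
    warmup: int = 1000,
    thin: int = 4,
    seed: int = 0,
    prior_only: bool = False,
    target_accept: float = 0.85,
    max_leapfrog: int = 48,
) -> DHMMPosterior:
    """Draw from the DHMM posterior by Hamiltonian Monte Carlo.

    Defaults reproduce the long-run convention (4 chains x 5000
    iterations, 1000 warmup, thinning 4 -> 4000 kept draws); the ``desk``
    entry of :data:`MCMC_PRESETS` keeps the same draw count from shorter
    unthinned chains.  ``prior_only=True`` switches the likelihood off,
    which is the standard prior-recovery validation of the sampler.
    """
    md = _prepare_data(spec, data)
    if not prior_only:
        occ_per_ind = np.bincount(md.idx)
        if len(md.individuals) < 2 or (occ_per_ind >= 2).sum() < 2:
            raise ValueError(
                "need >= 2 individuals with >= 2 occasions each to separate "
                "between- from within-individual variance"
            )
    post = _Posterior(md, likelihood=not prior_only)

    all_draws = []
    accept_rates = []
    for chain_rng in [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(chains)
    ]:
        draws, acc = _hmc_chain(
            post,
            _initial_theta(post, chain_rng),
            iterations=iterations,
            warmup=warmup,
            thin=thin,
            rng=chain_rng,
            target_accept=target_accept,
            max_leapfrog=max_leapfrog,
        )
        all_draws.append(draws)
        accept_rates.append(acc)
    theta = np.stack(all_draws)  # (chains, draws, dim)
    nc, nd, _ = theta.shape
    pm, pr = post.pm, post.pr

    beta = theta[:, :, :pm]
    gamma = theta[:, :, pm : pm + pr]
    s = np.exp(theta[:, :, pm + pr : pm + pr + 3])
    wc = np.tanh(theta[:, :, pm + pr + 3 : pm + pr + 6])
    z = theta[:, :, pm + pr + 6 :].reshape(nc, nd, post.n_ind, 3)

    # implied correlations R = L L' from the CPCs, vectorized over draws
    w0, w1, w2 = wc[..., 0], wc[..., 1], wc[..., 2]
    q = np.sqrt(1.0 - w1 * w1)
    r_ab = w0
    r_aw = w1
    r_bw = w0 * w1 + w2 * q * np.sqrt(1.0 - w0 * w0)

    params: dict[str, np.ndarray] = {"beta0": beta[:, :, 0], "gamma0": gamma[:, :, 0]}
    for k, term in enumerate(spec.mean_terms):
        params[f"beta[{term}]"] = beta[:, :, k + 1]
    for k, term in enumerate(spec.residual_terms):
        params[f"gamma[{term}]"] = gamma[:, :, k + 1]
    params["sd_intercept"] = s[:, :, 0]
    params["sd_time"] = s[:, :, 1]
    params["omega"] = s[:, :, 2]
    params["r_intercept_slope"] = r_ab
    params["r_intercept_omega"] = r_aw
    params["r_slope_omega"] = r_bw

    # random effects on the natural scale: r_i = z_i (diag(s) L)'
    re = np.empty_like(z)
    for c in range(nc):  # per-chain loop keeps memory modest
        L = np.zeros((nd, 3, 3))
        L[:, 0, 0] = 1.0
        L[:, 1, 0] = wc[c, :, 0]
        L[:, 1, 1] = np.sqrt(1.0 - wc[c, :, 0] ** 2)
        L[:, 2, 0] = wc[c, :, 1]
        qq = np.sqrt(1.0 - wc[c, :, 1] ** 2)
        L[:, 2, 1] = wc[c, :, 2] * qq
        L[:, 2, 2] = qq * np.sqrt(1.0 - wc[c, :, 2] ** 2)
        M = s[c, :, :, None] * L
        re[c] = np.einsum("dik,dmk->dim", z[c], M)

    return DHMMPosterior(
        spec=spec,
        params=params,
        random_effects=re,
        individuals=md.individuals,
        accept_rates=tuple(accept_rates),
        n_dropped_rows=md.n_dropped,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Split-chain R-hat and ESS per population-level parameter."""

    table: pd.DataFrame  # columns: parameter, rhat, ess, ok
    rhat_threshold: float = RHAT_THRESHOLD
    ess_threshold: float = ESS_THRESHOLD

    @property
    def passed(self) -> bool:
        return bool(self.table["ok"].all())

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        worst = self.table.loc[self.table["rhat"].idxmax()]
        return (
            f"convergence {status}: max R-hat {worst['rhat']:.4f} "
            f"({worst['parameter']}), min ESS {self.table['ess'].min():.0f} "
            f"(thresholds: R-hat < {self.rhat_threshold}, ESS > {self.ess_threshold})"
        )


def diagnose(posterior: DHMMPosterior | dict[str, np.ndarray]) -> ConvergenceReport:
    """Split-chain R-hat and effective sample size for every population
    parameter; passes iff R-hat < 1.01 and ESS > 400 throughout."""
    import arviz as az

    params = posterior.params if isinstance(posterior, DHMMPosterior) else posterior
    first = next(iter(params.values()))
    if first.ndim != 2 or first.shape[0] < 2:
        raise ValueError("split R-hat needs >= 2 chains of draws")
    if first.shape[1] < 100:
        raise ValueError("need >= 100 kept draws per chain for stable diagnostics")
    idata = az.from_dict(posterior=params)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for name in params:
        r = float(rhat[name].values)
        e = float(ess[name].values)
        rows.append(
            {
                "parameter": name,
                "rhat": r,
                "ess": e,
                "ok": bool(r < RHAT_THRESHOLD and e > ESS_THRESHOLD),
            }
        )
    report = ConvergenceReport(table=pd.DataFrame(rows))
    if not report.passed:
        logger.warning("%s", report)
    return report


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval: the shortest contiguous interval
    containing the requested posterior mass."""
    draws = np.sort(np.asarray(draws, dtype=float).ravel())
    n = draws.size
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    if n < 100:
        raise ValueError(f"need >= 100 draws to resolve an HPD interval, got {n}")
    m = int(np.ceil(mass * n))
    if m >= n:
        raise ValueError(f"too few draws to resolve a {mass:.0%} interval")
    widths = draws[m - 1 :] - draws[: n - m + 1]
    k = int(np.argmin(widths))
    return float(draws[k]), float(draws[k + m - 1])


__all__ = [
    "ConvergenceReport",
    "DHMMPosterior",
    "DHMMSpec",
    "ESS_THRESHOLD",
    "MCMC_PRESETS",
    "POPULATION_PARAMS",
    "RHAT_THRESHOLD",
    "STUDY_COVARIATES",
    "dhmm_loglik",
    "diagnose",
    "hpd_interval",
    "sample_dhmm",
]
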