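"""Repeatability, coefficient of predictability and type–predictability links.

All statistics are computed per posterior draw and then summarized
(posterior mean and 95% highest-posterior-density interval), which is the
convention the reported estimates imply; a plug-in evaluation at posterior
means differs by the Jensen gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dhmm import DHMMPosterior, hpd_interval


@dataclass
class RepeatabilityEstimate:
    """Adjusted repeatability R = V_individual / (V_individual + V_residual).

    V_individual is the between-individual variance sd_intercept^2 of the
    mean submodel; V_residual is the residual variance of a
    population-typical individual, obtained from the residual-model
    intercept by exponentiating (the dispersion model works on the log-SD
    scale) and squaring: (exp(gamma0))^2.
    """

    mean: float
    hpd: tuple[float, float]
    draws: np.ndarray
    v_individual: np.ndarray
    v_residual: np.ndarray


@dataclass
class PredictabilityEstimate:
    """CV_P summary plus per-individual rIIV (residual SD) posteriors.

    CV_P = sqrt(exp(omega^2) - 1) is the coefficient of variation of the
    individual residual SDs implied by the lognormal dispersion random
    effect; larger values mean individuals differ more in predictability.
    ``riiv`` holds exp(gamma0 + w_i) draws per individual — an
    individual's residual SD around its behavioural mean, low values
    meaning high predictability.
    """

    mean: float
    hpd: tuple[float, float]
    draws: np.ndarray
    riiv: np.ndarray  # (n_draws, n_individuals)
    individuals: np.ndarray


@dataclass
class CorrelationSummary:
    """Posterior of one random-effect correlation with its significance flag
    (95% HPD interval excluding zero)."""

    parameter: str
    mean: float
    hpd: tuple[float, float]
    significant: bool
    draws: np.ndarray


def repeatability(posterior: DHMMPosterior) -> RepeatabilityEstimate:
    """Per-draw adjusted repeatability from a fitted location–scale model."""
    for name in ("sd_intercept", "gamma0"):
        if name not in posterior.params:
            raise KeyError(f"posterior lacks required parameter {name!r}")
    sd_i = posterior.stacked("sd_intercept")
    gamma0 = posterior.stacked("gamma0")
    v_ind = sd_i**2
    v_res = np.exp(gamma0) ** 2
    r = v_ind / (v_ind + v_res)
    return RepeatabilityEstimate(
        mean=float(r.mean()),
        hpd=hpd_interval(r),
        draws=r,
        v_individual=v_ind,
        v_residual=v_res,
    )


def cv_p(omega) -> float | PredictabilityEstimate:
    """Coefficient of predictability CV_P = sqrt(exp(omega^2) - 1).

    ``omega`` is the SD of the dispersion random intercept (log-residual-SD
    scale).  A scalar input returns a scalar; a :class:`DHMMPosterior`
    returns the per-draw summary together with the per-individual rIIV
    posterior exp(gamma0 + w_i).
    """
    if isinstance(omega, DHMMPosterior):
        posterior = omega
        om = posterior.stacked("omega")
        draws = np.sqrt(np.expm1(om**2))
        gamma0 = posterior.stacked("gamma0")
        w = posterior.random_effects[:, :, :, 2].reshape(-1, len(posterior.individuals))
        riiv = np.exp(gamma0[:, None] + w)
        return PredictabilityEstimate(
            mean=float(draws.mean()),
            hpd=hpd_interval(draws),
            draws=draws,
            riiv=riiv,
            individuals=posterior.individuals,
        )
    om = np.asarray(omega, dtype=float)
    if np.any(om < 0):
        raise ValueError("omega is a standard deviation and must be >= 0")
    out = np.sqrt(np.expm1(om**2))
    return float(out) if out.ndim == 0 else out


def type_predictability_correlation(posterior: DHMMPosterior) -> CorrelationSummary:
    """Correlation between behavioural type (mean-model random intercept)
    and rIIV (dispersion random intercept).

    A negative value means individuals with higher trait means have lower
    rIIV, i.e. are *more* predictable (low rIIV = high predictability).
    """
    if "r_intercept_omega" not in posterior.params:
        raise KeyError("posterior lacks the intercept–omega correlation draws")
    r = posterior.stacked("r_intercept_omega")
    lo, hi = hpd_interval(r)
    return CorrelationSummary(
        parameter="r_intercept_omega",
        mean=float(r.mean()),
        hpd=(lo, hi),
        significant=bool(lo > 0.0 or hi < 0.0),
        draws=r,
    )


__all__ = [
    "CorrelationSummary",
    "PredictabilityEstimate",
    "RepeatabilityEstimate",
    "cv_p",
    "repeatability",
    "type_predictability_correlation",
]
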