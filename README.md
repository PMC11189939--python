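# thermopred

Animal personality and predictability in thermoregulatory and "classic"
behavioural traits of heliothermic lizards — a reusable, tested Python
implementation of the full analysis pipeline: trait derivation from raw
observation logs, double-hierarchical (location–scale) mixed models,
repeatability and coefficient-of-predictability statistics, and
between-/within-individual correlation decomposition for
behavioural-syndrome detection.  A calibrated synthetic-data generator
emulates the study design (36 adult male *Zootoca vivipara*, 6 thermal
assay days × 22 half-hourly body-temperature readings, 5 behavioural assay
days, state covariates), so everything runs end to end from a single seed
with no external data.

## Who this is for

Behavioural ecologists and biostatisticians quantifying *behavioural
type* (an individual's mean behaviour), *behavioural predictability*
(the inverse of its residual intra-individual variation, rIIV) and
*behavioural syndromes* (between-individual trait correlations) from
repeated-measures assays.

## The model

Each trait `y_ij` (individual `i`, occasion `j`) follows a
double-hierarchical Gaussian model pairing a **mean** and a **residual
(dispersion)** submodel:

    y_ij ~ Normal(mu_ij, sigma_ij)
    mu_ij        = beta0 + x_ij' beta + a_i + b_i t_j        (mean model)
    log sigma_ij = gamma0 + x_ij' gamma + w_i                (residual model)

with `(a_i, b_i, w_i) ~ MVN(0, diag(s) R diag(s))`,
`s = (sd_Intercept, sd_Time, omega)`.  `a_i` is the behavioural type,
`b_i` the individual habituation slope on the standardized test day
`t_j`, and `w_i` the individual offset of the log residual SD — its SD
`omega` measures how much individuals differ in predictability.
Priors: Normal(0,1) on fixed effects, half-Normal(0,1) on the SDs, LKJ(1)
on `R`.  Derived statistics, computed per posterior draw:

* adjusted repeatability `R = V_ind / (V_ind + V_res)` with
  `V_ind = sd_Intercept^2` and `V_res = (exp(gamma0))^2`;
* coefficient of predictability `CV_P = sqrt(exp(omega^2) - 1)`;
* the type–predictability correlation `r(a, w)` (negative values mean
  individuals with higher trait means are *more* predictable).

A six-trait multivariate mixed model
`y_ij = mu + u_i + e_ij`, `u_i ~ MVN(0, Sigma_B)`, `e_ij ~ MVN(0, Sigma_W)`
decomposes phenotypic correlations into between-individual (syndrome)
and within-individual parts.

Thermal traits per individual-day: **T_sel** (median body temperature),
**T_set** (width of the central 50% of readings; thermoregulatory
precision) and **T_Vmax** (highest temperature voluntarily reached).
Behavioural traits per trial: movement **activity**
(`transitions / seconds outside × 60`), **sheltering** (log seconds
hiding) and **risk-taking** (log latency to emerge after a simulated
attack).

## Worked example

```sh
thermopred all --seed 1 --scale desk
```

runs simulate → derive → per-trait DHMM fits → statistics → multivariate
decomposition → report into `thermopred_run/` (about two minutes; the
`paper` scale restores the long-run MCMC conventions).  The same in
Python:

```python
from thermopred import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(outdir="demo_run", seed=1, scale="desk"))
print(report.statistics.round(3))
```

With seed 1 the statistics table starts:

```
      trait  repeatability  repeatability_low  repeatability_high  cv_p  cv_p_low  cv_p_high
      T_sel          0.313              0.148               0.497 0.202     0.000      0.405
 sheltering          0.752              0.624               0.882 0.365     0.070      0.605
risk_taking          0.545              0.338               0.743 0.468     0.210      0.766
```

so, e.g., sheltering is highly repeatable in this synthetic cohort
(R = 0.75 [0.62, 0.88]: three quarters of its phenotypic variance is
between individuals) and individuals clearly differ in risk-taking
predictability (CV_P = 0.47 [0.21, 0.77]: the individual residual SDs
have a coefficient of variation near one half).  The correlation
decomposition flags a between-individual T_sel–T_Vmax syndrome
(r = 0.64 [0.36, 0.84]) — individuals selecting higher temperatures also
reach higher voluntary maxima, a structural feature of the generator —
and every fit carries a split-chain R-hat / effective-sample-size report
(thresholds 1.01 and 400); non-converged fits are flagged in the report,
never dropped.

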