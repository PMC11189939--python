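# Methods

This note documents the statistical models, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Trait derivation

* **Thermal traits** are computed per individual-day from the ordered
  half-hourly body temperatures: T_sel = median, T_Vmax = maximum,
  T_set = 75th − 25th percentile (the width of the central 50%).
  Quantiles interpolate linearly between order statistics — the common
  default in mainstream statistical environments — and the convention is
  pinned by oracle tests.  Series shorter than 4 readings are rejected
  (quartiles are not meaningfully resolved).
* **Movement activity** = (grid-square transitions / seconds outside the
  shelter) × 60, a per-minute rate independent of sheltering.  A trial in
  which the animal never left the shelter has no defined rate and is
  recorded as missing; transitions with zero time outside are an
  inconsistent record and an error.  Field reports sometimes quote raw
  transition *counts* instead of this rate; the pipeline computes the
  rate, and the two differ by the factor time-outside/60.
* **Sheltering** and **risk-taking latency** enter the models as
  log(seconds + 1).  The offset guards legitimate zero durations and is
  monotone; with typical durations (tens to hundreds of seconds) it is
  numerically negligible.  Latencies are censored at the 3600-s recording
  length and the censored value is used as-is.
* **State covariates**: head size is the first principal component of the
  correlation-matrix PCA on pileus length, pileus width and maximum head
  width (sign fixed so all loadings are positive); relative head size and
  body condition are ordinary least-squares residuals of head-size PC and
  body weight on SVL (raw scales); parasite intensity is the mean
  infected-cell count of three smear scans.
* All responses and continuous covariates are z-scored (sample SD,
  ddof = 1); the (mean, SD) pairs are retained so fitted intercepts can
  be returned to natural units.
* Thermal and behavioural assay days alternate; the trait table interleaves
  them as occasions, each row carrying one trait block and missing values
  for the other.  The `time` covariate is the z-scored assay index within
  each block.

## The double-hierarchical model

Mean model: intercept, time (habituation), SVL, relative head size,
condition, parasite load, and the three parasite × size interactions;
random intercept `a_i` and random time slope `b_i`.  Residual model: the
same fixed effects *without* time; random intercept `w_i` on the
log-residual-SD scale.  `(a, b, w)` are jointly normal with SDs
`(sd_Intercept, sd_Time, omega)` and an unstructured 3×3 correlation.
Priors: Normal(0,1) fixed effects, half-Normal(0,1) SDs, LKJ(1)
correlation.  Rows with a missing response or covariate are dropped per
response, with the count logged.

### Sampler

Hamiltonian Monte Carlo with analytic gradients on the unconstrained
scale:

* non-centred random effects (`r_i = diag(s) L z_i`, `z_i ~ N(0, I)`),
  the standard remedy for the funnel geometry at small SDs;
* log-transformed SDs with the Jacobian term;
* the correlation Cholesky factor `L` parameterised by canonical partial
  correlations through `tanh`; under LKJ(1) in dimension 3 the partial
  correlations are independent Beta(1.5, 1.5) / Beta(1, 1) variates on
  (−1, 1), which gives a two-line exact prior gradient;
* dual-averaging step-size adaptation (target acceptance 0.85) with a
  diagonal mass matrix estimated from the middle warmup window, and
  uniformly jittered leapfrog path lengths (1..48) against periodicity;
* the gradient is verified against finite differences in the test suite.

Two length presets keep 4000 draws each: `paper` (4 chains × 5000
iterations, 1000 warmup, thinning 4 — the long-run convention) and `desk`
(4 × 1500, 500 warmup, unthinned), the package default for interactive
work.  Convergence is assessed per population-level parameter with
rank-normalised split-chain R-hat and effective sample size (via arviz),
thresholds R-hat < 1.01 and ESS > 400; failures are flagged prominently
and never silently dropped.  Point estimates are posterior means;
intervals are 95% highest-posterior-density (shortest-window) intervals.

### Derived statistics

All statistics are computed per posterior draw, then summarised — the
plug-in evaluation at posterior means differs by a Jensen gap (e.g. the
plug-in CV_P for a dispersion SD of 0.59 is 0.645, while per-draw
averaging typically lands slightly lower).  Repeatability converts the
residual-model intercept alone (`V_res = (exp(gamma0))^2`, the residual
variance of a population-typical individual with covariates at their
means); individual rIIV posteriors are `exp(gamma0 + w_i)`.

## Multivariate model and syndrome decomposition

`y_ij = mu + u_i + e_ij` over the six standardized traits, fitted by
blocked Gibbs sampling with conjugate updates: flat prior on `mu`,
inverse-Wishart(p + 1, I) on both covariance matrices (weakly
informative: identity scale, minimal proper degrees of freedom, implying
marginally uniform correlations).  The alternating assay design means the
thermal and behavioural blocks never co-occur within an occasion row;
the missing block is augmented from its Gaussian conditional each sweep,
which targets the same posterior as marginalising the likelihood over
the observed subvector while keeping every update conjugate.  Because the
blocks share no occasions, within-individual cross-block correlations
are only indirectly informed and should be read with caution.

Correlations are computed per draw from the covariance draws and
summarised by the mean and a central 95% quantile interval (the
convention of the conjugate-Gibbs fitting tradition; the per-trait DHMMs
use HPD intervals — both are labelled).  A pair is flagged as a syndrome
when the between-individual interval excludes zero.  When reading all 15
pairs at once, note that ~0.75 null pairs are expected to exclude zero by
chance at the 95% level; the flags are per-pair statements, not a
family-wise test.  Run presets: `paper` = 1,300,000 iterations, 300,000
burn-in, thinning 1000; `desk` = 20,000 / 5,000 / 15 — both keep ~1000
draws.

## Synthetic-data generator

The generator is the model run forwards, calibrated to the study
population:

* **Design**: 36 adult males, 6 thermal days × 22 readings (every 30 min,
  8:00–18:30), 5 behavioural days, thermal gradient 23–60 °C.
* **Covariates**: SVL 5.2 ± 0.63 cm; body weight 4.39 ± 0.67 g
  (correlation 0.7 with SVL, so the condition residual is meaningful);
  head measures 1.11 ± 0.059, 0.64 ± 0.03, 0.80 ± 0.057 cm with
  equicorrelation 0.4419, chosen so the first principal component carries
  (1 + 2ρ)/3 = 62.79% of the variance with all-positive loadings;
  parasite prevalence 0.806 with infected intensities from a lognormal
  moment-matched to a population mean ± SD of 4.75 ± 4.34 per 1000 RBC
  (the near-equal mean and SD imply right skew), counted by three Poisson
  smear scans.
* **Within-day temperatures** are Normal around the individual-day T_sel
  target with SD = T_set target / 1.349 (the normal IQR), truncated to
  the gradient bounds, so the day's median and central-50% width match
  the targets in expectation; T_Vmax has no dial of its own — it emerges
  as the within-day maximum, which lands near the reported population
  average.  Truncation alters well under 1% of readings at the default
  calibration; a warning fires beyond that.
* **Trait-level calibration** (natural scales): population means at the
  reported averages (T_sel 32.22 °C, T_set 4.49 °C, activity 6.84/min,
  sheltering 75.4 s, risk latency 195.6 s); between-individual SDs set so
  ~36 individual means span the reported ranges; residual scales and
  dispersion-SD magnitudes follow the location–scale estimates.
* **Occasions** use the z-scored day index as the time covariate.
* **Seeding**: one master seed; per-module streams are spawned
  deterministically, so identical (config, truth, seed) give
  bit-identical datasets.

What the generator does **not** emulate: time-of-day structure within
assays (the study randomised recording blocks and did not model it);
any spatial thermal-gradient physics; and — in the raw-level generator —
cross-trait coupling: each trait's location–scale model is drawn
independently, so raw-data runs carry no built-in behavioural syndrome
(T_sel–T_Vmax and T_set–T_Vmax correlations still arise structurally from
the within-day construction).  Syndrome structure is generated at the
trait level via `simulate_multitrait_table`, whose
`study_syndrome_covariances()` preset encodes the reported
between-individual sign pattern (activity–sheltering −0.77,
sheltering–risk-taking 0.64, T_sel–T_Vmax 0.45, …; the matrix is nudged
onto the PSD cone and renormalised if the printed pattern is marginally
indefinite).  Passing tests on synthetic data therefore validate the
estimators under the assumed generative model, not the biology of any
real population.

## Numerical and testing choices

* Tables are plain delimited text; floats are written with `%.17g` and
  read with round-trip precision, so write-then-read is bit-exact.
* HPD intervals require ≥ 100 draws; the shortest window is found by an
  exhaustive scan over order statistics.
* Posterior-parameter recovery is validated at the study scale (36 × 6)
  over 20 replicates, and the multivariate decomposition at 200
  individuals × 8 occasions — sizes at which the estimands are
  well-identified while a full validation run stays at desk scale.
* Degenerate inputs fail loudly by name: non-PSD correlation inputs,
  zero-variance columns, constant PCA columns, traits observed on < 2
  occasions for every individual, inconsistent behaviour records.

## Known limitations

* Single-response DHMMs and a covariate-free multivariate stage; no
  generalised (non-Gaussian) responses, no model comparison criteria.
* The dispersion submodel shares the mean submodel's covariates (minus
  time) by construction; alternative residual-model specifications
  require a custom `DHMMSpec`.
* At desk MCMC lengths an occasional fit can miss the convergence
  thresholds (it is flagged in the report); the `paper` preset resolves
  this at ~4× the cost.
* Risk-taking censoring is handled by value substitution, not by a
  censored likelihood.
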