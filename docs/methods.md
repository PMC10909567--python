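# Methods

This note documents the models implemented in `coralipm`, the choices made
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## State variable and vital rates

Colony state is z = ln(horizontal surface area in cm²). Natural logs are
used throughout (the base only rescales coefficients). All size-dependent
rates are regressions on z, fitted per assemblage:

| rate | model | default form |
|---|---|---|
| survival σ(z) | logistic GLM | linear in z |
| growth γ(z′\|z) | Gaussian, polynomial mean | quadratic; constant residual sd |
| fragmentation κ(z) | logistic GLM | quadratic (see small-sample guard) |
| remnant count κ_b(z) | 1 + Poisson GLM (log link) | linear in z, capped |
| remnant size κ_z0(z′\|z) | truncated-Gaussian MLE | linear mean, constant sd |
| fecundity φ(z) | least squares on log output | quadratic |
| settlement ϕ | recruits ÷ predicted larvae, per year | pooled mean of yearly ratios |
| recruit sizes C0 | Gaussian on log scale | sd floor 0.05 |

Notes on the open choices:

* **Polynomial degree.** "Polynomial" is under-determined; quadratic is the
  minimal curvature-capable choice and is the default for growth,
  fragmentation and fecundity. Degrees are arguments everywhere.
* **Fragmentation conditioning.** Fragmentation is modeled conditional on
  survival (an observed breakage with no surviving remnant is recorded as a
  death). The kernel's fragmentation term carries no survival factor by
  default — matching the kernel definition above — and a
  `sigma_on_fragmentation` switch multiplies it by σ(z) for sensitivity
  analysis.
* **Remnant sizes are upper-truncated.** A remnant cannot exceed the colony
  it broke from, so remnant log-sizes follow a Gaussian truncated above at
  the parent's z. Ordinary least squares is biased under truncation
  (measurably so: the intercept shifts by ~0.2 log units at realistic
  parameters), so the fit is a truncated-normal maximum likelihood with
  analytic gradient; standard errors come from the inverse observed
  information. The kernel discretization truncates the remnant density at
  the parent midpoint and renormalizes.
* **Settlement direction.** The yearly ratio is recruits divided by total
  predicted larval output — the only direction that yields a probability.
  Years are matched on the transition-start year.
* **Random effects.** The fitting default is fixed-effects-only; an
  optional site random intercept is available for survival (variational
  Bayes binomial mixed GLM) and growth (linear mixed model). The generator
  has no site-level heterogeneity by default, so marginal predictions move
  by well under 10% on balanced synthetic data; full crossed random effects
  are out of scope.
* **Small-sample guards.** Two fitted quantities extrapolate dangerously
  when fragmentation events are scarce: the quadratic fragmentation logit
  (degree backs off to linear below 30 events and intercept-only below 10)
  and the remnant-count regression (mean predictions are capped at twice
  the largest observed count). Without these, sampling noise at a few
  hundred colonies occasionally produces a survival/fragmentation kernel
  with spectral radius ≥ 1 — an immortal-colony artifact under which the
  net reproductive rate is undefined. `build_kernel` still refuses such
  kernels outright.
* **Separation.** Logistic fits detect complete or quasi-separation and
  fall back to a lightly ridge-penalized IRLS fit, flagged on the model.
* **Fitting engines.** `statsmodels` is the default engine; a numpy IRLS
  engine produces the same estimates (checked to 1e-7 in the tests) and is
  used inside resampling loops, where fitting cost dominates.

## Kernel discretization

The domain [L, U] is the observed raw size range widened multiplicatively
by 10% each way (additive widening could cross zero), then
log-transformed. The midpoint rule on m = 200 cells (entry = kernel at
midpoints × cell width) discretizes the kernel. Probability mass of the
growth and remnant-size densities falling outside [L, U] is binned into the
nearest boundary cell and each density column is normalized to total 1:
with fragmentation off, the columns of P then sum exactly to σ at the
midpoints (no eviction leak), and each column of F sums to φ(z)·ϕ. Remnant
production can push column masses of P above 1 (one parent, several
remnants); that is intentional and not clamped. λ changes by well under
1e-3 between m = 200 and m = 400 on all preset kernels.

## Transient metrics

All indices are computed on the λ-normalized matrix A = K/λ, whose column
sums correspond to stage-biased (single-size-class) initial structures.

* **Damping ratio**: λ₁/|λ₂| with eigenvalues ordered by modulus; ties
  (imprimitive matrices) are flagged, a zero subdominant modulus returns an
  infinite sentinel.
* **Maximal amplification**: the running maximum of the column sums of A^t,
  iterated as a vector recurrence; iteration stops when the per-step
  maximum has been non-increasing for 50 consecutive steps (cap 10,000,
  error on no convergence — periodic matrices genuinely never settle).
  Verified against explicit matrix-power enumeration.
* **Kreiss bounds**: (r−1) × extreme column sums of the resolvent
  (rI − A)⁻¹, optimized over r > 1 on the log₁₀(r−1) scale: a 300-point
  scan over r−1 ∈ [1e−6, 1e3] followed by bounded scalar refinement
  (tolerance 1e-9, ties toward smaller r). Each evaluation is one linear
  solve. The attenuation bound is often approached as r → 1⁺ (its limit is
  the smallest stage-biased long-run density); a bound pinned at the probe
  boundary *and* indistinguishable from zero signals reducible-like
  structure and is flagged. An eigendecomposition-based dense-grid oracle
  (10⁵ points) guards the optimizer in the tests.
* **R0 and generation time**: R0 = ρ(F(I−P)⁻¹), T = log R0/log λ, with
  ρ(P) < 1 enforced. Verified against an individual-based lifetime-offspring
  simulation (F is rank one, so R0 is the mean lifetime output of a recruit
  drawn from C0).

## Jackknife uncertainty

The resampling unit is the colony: each of the (default 1000, commonly 200
at test scale) replicates keeps 95% of colonies, refits the colony-based
rates, draws ϕ uniformly between the observed yearly minimum and maximum,
rebuilds the kernel and recomputes metrics. Fecundity tables and recruit
sizes are not colony data and are fitted once on the full inputs.
Replicates with λ > 2 (implausible, more-than-doubling populations) are
excluded and counted; generation time is log-transformed; power transforms
ρ⁻²·⁰, TE⁻⁰·¹ and ρ̄max⁻⁰·⁵ bring the remaining metrics toward normality.
The last is reported as the demographic stability index (DSI); the TE and
DSI scales are order-reversing.

Two interval types are offered. Percentile intervals of the replicate
distribution are the default reported summary (they commute with the
monotone transforms and describe ensemble spread). They are **not**
calibrated confidence intervals: deleting only 5% of colonies shrinks the
replicate spread to roughly √(d/(n−d)) ≈ 0.23 of the estimator's sampling
sd, so raw percentile intervals cover the data-generating value far below
nominal rate (~35% in our experiments). `delete_d_interval` applies the
standard delete-d variance scaling (n−d)/d and is the package's calibrated
95% interval; it covers the generative λ at ~95% in the coverage
experiment (100 runs × 200 replicates at 1000 colonies) run by the
acceptance tests.

## Thermal regimes

SST series are monthly, 840 months by convention (a 69–70 year window).
The spectral exponent is the OLS slope of log₁₀ raw periodogram density on
log₁₀ frequency over k/n for k = 1..⌊n/2⌋. No tapering, smoothing or
deseasonalization is applied by default — the annual cycle stays in the
spectrum; a `deseasonalize` flag subtracts monthly means for sensitivity
checks, and ordinates that are zero to numerical precision (exact zeros or
nulled harmonics) are dropped from the regression with a warning. A fit
explaining under 10% of log-spectral variance (single-line spectra) is
flagged. The estimator is calibrated on spectral-synthesis series: mean
estimates over 50 seeds land within ±0.2 of targets β ∈ {−2, −1, 0}.

## Comparative statistics

* **PLSR**: two-block NIPALS with deflation of both blocks on standardized
  inputs (tolerance 1e-10, 500 iterations max), two components reported.
  X-variance per component is ‖t p′‖²_F/‖X‖²_F; ry2 is the cumulative
  Y-variance captured. Predictor collinearity is reported (pairwise
  correlations, condition number), never auto-fixed. The single-response
  case reduces to the dominant singular vector of X′y, and scikit-learn's
  implementation serves as an independent cross-check in the tests.
* **Ranged major axis**: both variables scaled to [0, 1] by their ranges,
  major-axis slope on that scale, back-transformed by range(y)/range(x);
  the line passes through the means; r² is the squared Pearson correlation.
  Checked against direct perpendicular-distance minimization.
* **Factorial ANOVA**: country × ecoregion × strategy with Type II sums of
  squares (the ensembles are mildly unbalanced after the λ-filter, and
  Type II is the conventional default there), requiring ≥ 2 observations
  per cell; Tukey HSD on the interaction cells, with the
  tropical-vs-subtropical contrasts within each country × strategy cell
  extracted as the primary view. Using jackknife replicates as observations
  inflates denominator degrees of freedom enormously; the package follows
  that analysis design but the resulting p-values should be read as
  descriptive.

## The synthetic generator

`simulate_survey` draws, per colony-year: Bernoulli survival on the
logistic curve; Bernoulli fragmentation (conditional on survival by
default; a switch removes the conditioning); Gaussian growth for
non-fragmenting survivors; a zero-truncated Poisson remnant count and
parent-truncated Gaussian remnant sizes for fragmenting ones (the colony
continues as its largest remnant). Yearly recruit counts are Poisson on
ϕ_true × the standing assemblage's expected larval output; parameter sets
implying mean survival below 1% are refused as degenerate. `simulate_sst`
synthesizes 1/f^|β| noise by setting Fourier amplitudes ∝ f^(β/2) with
uniform random phases, rescaling exactly to the target mean and sd, with an
optional annual sinusoid.

Twelve presets (4 regions × 3 strategies) mirror a two-country,
tropical/subtropical study design: fast-growing competitive, slow
high-survival stress-tolerant and fast-turnover weedy assemblages, a
survival edge for the tropical member of each pairing (reversed for the
Japanese weedy pairing), and regional SST presets in which subtropical
regions are cooler, more variable and spectrally whiter. Preset survival
keeps the true P-kernel's spectral radius at or below ~0.96: values closer
to 1 are biologically defensible for stress-tolerant corals but leave no
headroom for sampling noise in fitted kernels. Default test-scale sizes
(hundreds of colonies per assemblage, three transitions, 200 jackknife
replicates) were chosen so the full study runs in minutes on one CPU.

What the generator does **not** emulate: site- or colony-level random
effects, temporal environmental drivers of the vital rates (SST series are
generated independently of demography, so cross-block associations in the
comparative layer are incidental rather than mechanistic), taxonomic
composition within strategies, observation error in sizes, and spatial
structure. Passing tests therefore demonstrate the estimators recover the
assumed statistical structure — not that real surveys satisfy it.

## Known limitations

* The fragmentation term follows the kernel definition literally (no
  survival factor); the alternative reading is one switch away but changes
  λ only marginally at realistic fragmentation rates.
* Kreiss-bound probe range r−1 ∈ [1e−6, 1e3] bounds the attenuation limit
  from above by its value near r = 1; matrices whose attenuation limit
  varies on finer scales than 1e-6 would need a wider grid.
* The ϕ ratio treats predicted larval output as error-free; uncertainty in
  φ propagates into ϕ only through the jackknife's uniform redraw.
* GLMM machinery beyond a site random intercept (crossed colony/site
  effects, temporal effects, model selection) is deliberately absent.
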