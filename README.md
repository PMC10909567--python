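# coralipm

Size-structured demography of coral assemblages: integral projection models
(IPMs) with colony fragmentation, long-term and transient performance
metrics, jackknife uncertainty, thermal-regime characterization, and the
comparative statistics that relate demography to environment. The package is
aimed at population ecologists who want to ask whether assemblages exposed
to more variable thermal environments trade long-term performance (growth
rate λ) for short-term potential (demographic amplification), and at
methodologists who need tested implementations of transient indices —
damping ratio, maximal amplification, Kreiss bounds, transient envelope —
for large discretized kernels.

Because longitudinal tagged-colony data are hard to ship, a first-class
synthetic-data module generates surveys, recruit counts, fecundity tables
and sea-surface-temperature (SST) series with the statistical structure the
analysis assumes, so every stage runs and is tested offline.

## The model

Colony state is z = ln(horizontal surface area, cm²). The population
structure n(z, t) evolves as

    n(z', t+1) = ∫_L^U [P(z'|z) + F(z'|z)] n(z, t) dz

with a survival/growth/fragmentation kernel and a reproduction kernel

    P(z'|z) = (1 − κ(z)) σ(z) γ(z'|z) + κ(z) κ_b(z) κ_z0(z'|z)
    F(z'|z) = φ(z) · ϕ · C0(z')

where σ is logistic survival, γ a Gaussian growth kernel with polynomial
mean, κ the polynomial-logistic fragmentation probability, κ_b the expected
remnant count (zero-truncated Poisson), κ_z0 the remnant size density
(truncated below the parent size), φ the polynomial log-linear fecundity,
ϕ the per-larva settlement probability and C0 the recruit size density.
The domain [L, U] spans 10% above and below the observed raw size range;
kernels are discretized by the midpoint rule on a 200 × 200 mesh with
evicted probability mass binned into the boundary cells.

From the discretized K = P + F the package computes λ (dominant
eigenvalue), damping ratio ρ = λ₁/|λ₂|, net reproductive rate
R0 = ρ(F(I − P)⁻¹), generation time T = log R0 / log λ, maximal
amplification ρ̄max = sup_t ‖(K/λ)^t‖₁, and the Kreiss bounds

    K̄ = sup_{r>1} (r−1) · max column sum (rI − K/λ)⁻¹
    K_ = inf_{r>1} (r−1) · min column sum (rI − K/λ)⁻¹

whose difference TE = K̄ − K_ (transient envelope) spans the possible
long-run deviation from the asymptotic trajectory. Uncertainty comes from a
colony-level jackknife (95% subsamples, settlement redrawn within observed
yearly limits); thermal regimes are summarized by the SST mean, coefficient
of variation and spectral exponent β (periodogram slope on log-log axes);
and the cross-assemblage layer offers two-block NIPALS PLSR, ranged major
axis (Type 2) regression and three-way factorial ANOVA with Tukey
contrasts.

## Worked example

```python
import warnings
from coralipm import (preset_params, simulate_survey, simulate_fecundity,
                      build_kernel, compute_all)
from coralipm.vital_rates import fit_all

params = preset_params("JT", "stress_tolerant", n_colonies=1200,
                       n_years=4, seed=3)
obs, recruits = simulate_survey(params)
fec = simulate_fecundity(params, 600, seed=4)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    rates = fit_all(obs, recruits, fec)
    kernel = build_kernel(rates, m=200)
    metrics = compute_all(kernel.P, kernel.F)
```

Running `python examples/02_kernel_and_metrics.py` (the same computation)
prints:

```
log-size domain [-0.09, 7.04], 200 cells of width 0.0357
lambda           0.9857   (>1 grows, <1 declines)
R0               0.6349   (lifetime offspring)
generation time  31.5 years
damping ratio    1.170   (recovery speed)
max amplification    4.365
Kreiss bounds    [0.090, 3.622]
transient envelope 3.532
```

A λ just below 1 marks a slowly declining assemblage; each individual
replaces itself with 0.63 offspring over a ~31-year generation. After a
disturbance that skews the size structure, the population can transiently
sit anywhere between 9% and 362% of the density its asymptotic trajectory
predicts — the 3.5-unit transient envelope is that leeway.

The other scripts in `examples/` cover fitting (01), jackknife uncertainty
(03), thermal regimes (04), the comparative layer (05) and the one-call
pipeline (06).

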