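# Methods

This note records the models implemented in `biocal`, their assumptions,
the defaults and why they were chosen, and the numerical decisions that a
maintainer would otherwise have to reverse-engineer from the code.

## Calibration models

A calibration model is the conditional distribution of a measurement
response given the independent quantity.  Throughout the package this is a
location-scale family: the location μ follows a parametric trend in the
independent variable, the scale follows a degree-0 or degree-1 polynomial in
μ (so noise grows with the signal, as in photometric assays), and the family
is either normal or Student-t.  The Student-t degree of freedom ν is treated
as one more constant to estimate; it is bounded below at 1 during
optimization because the likelihood surface for ν < 1 is badly behaved and
such extreme tails are not plausible for assay noise.

Trends:

* `polynomial` (constant term first, Horner evaluation),
* `asymmetric_logistic` — the five-parameter generalized logistic in the
  intuitive parametrization (L_L, L_U, I_x, S, c),
* `log_independent_asymmetric_logistic` — the same curve applied to
  log10(x), for responses like microbioreactor backscatter that are
  logistic in the logarithm of the biomass concentration.  Base 10 was
  chosen because calibration designs in this field are described in decades
  (standards "log-evenly spaced"); the base is recorded in the model JSON.

The classic form `f(x) = L_L + (L_U−L_L)(1+e^{−B(m−x)})^{−1/v}` maps to the
intuitive one by `c = ln v`, `I_x = m + ln(v)/B` (the root of the second
derivative) and `S = −B(L_U−L_L)(1+v)^{−(v+1)/v}` (the first derivative at
I_x).  The implementation evaluates the shared subexpressions once, computes
the power through `logaddexp` and clips exponents at ±500 so that extreme
arguments saturate to the curve limits instead of overflowing.

Estimation is bound-constrained maximum likelihood: L-BFGS-B from a
data-driven guess, followed by a Nelder-Mead polish (the box constraints
introduce kinks that defeat quasi-Newton steps near the boundary), with an
optional seeded multi-start.  The data-driven guess exploits the intuitive
parametrization: limits from the response range, inflection from the
midpoint crossing, slope from a linear fit through the central response
band.  Parameters that finish on a bound are flagged in `fit_info`.

`predict_independent` inverts a single observation through the monotone
trend (Brent root-finding on the calibrated range); responses outside the
calibrated response range are clipped to the nearest endpoint and flagged as
saturated rather than rejected, because saturated observations are a normal
occurrence in use.

Lack of fit is diagnosed with percentile occupancy: the predicted CDF
evaluated at each observation should be uniform for a well-specified model;
binned counts plus a chi-square test make trend, spread or tail
misspecification visible.  Diagnostic plots show the likelihood bands at
68/90/95% by default.

Persistence is JSON with fields `model_type`, `version`,
`independent_key`, `dependent_key`, the noise specification, `theta`,
guesses/bounds, and the calibration data.  Loading verifies the model-type
string against the noise specification and the major version; unknown
fields are ignored; missing calibration data is tolerated with a warning
(the model remains usable for prediction, but has no calibrated range).

## Posterior of the independent variable

Given observations y, the posterior under a uniform prior on [a, b] is
evaluated in three steps: (1) the summed log-likelihood is computed on a
coarse 10,000-point grid of [a, b], exponentiated after subtracting its
maximum (many observations would otherwise underflow), and normalized by
trapezoidal quadrature; (2) the 99.999% equal-tailed region is read off the
coarse CDF (smallest closed grid interval containing that mass); (3) the
density and CDF are re-evaluated on 100,000 points inside that region.  The
median and the ETI come from linear interpolation of the fine CDF.  The HDI
solves `min_a  F⁻¹(F(a)+p) − a`; because multimodal posteriors make this
objective multimodal, a 512-point pre-scan locates the basin and a bounded
1-D minimization refines it, which matches an exhaustive grid scan to one
grid step.

When bounds are not given they default to the calibrated range padded by
10% on each side, with the lower bound clipped at 0 when the calibration
concentrations are nonnegative — a uniform prior over negative
concentrations is unphysical and would smear posteriors for near-blank
responses.

## Dilution planning

The planner reshapes sorted target concentrations into the plate grid
column-major, with the most concentrated column first, and plans columns in
that order so that serial sources always exist before they are used.  Each
column is sourced from stock whenever all per-row transfer volumes fall in
the pipettable window; otherwise it is sourced from the feasible
already-planned column with the smallest dilution factor (largest transfer
volumes, hence smallest relative error).  Per-well volumes use the full
working volume unless the transfer would exceed the pipette maximum, in
which case the total is scaled down (a well whose target equals the stock
is filled with pure stock).  Volumes are rounded to 0.1 µL — a realistic
liquid-handler resolution — and the achieved concentrations are recomputed
from the rounded volumes by exact mass balance, so the reported
`max_relative_error` is the honest design error, not hidden rounding.

## Multi-replicate datasets and objectives

Data are held in three levels — `Timeseries` (t, y plus the independent and
dependent variable names), `Replicate` (one vessel), `Dataset` — and
persisted to HDF5 as `/replicates/{rid}/{dependent_key}/{t,y}` with the key
names as attributes.

A `ParameterMapping` table (rows = replicates, columns = model parameters)
assigns each slot a shared name, a replicate-local name, or a numeric
constant.  The flat estimation vector is ordered by lexicographically
sorted unique names; this is arbitrary but deterministic, which optimizer
restarts and trace columns require.  A name may appear in only one column.

The dataset objective solves each replicate once on the union of its
observed time grids and scores every observed series with the calibration
model registered for its dependent key (a per-replicate override map takes
precedence over the global map, so the same signal measured with different
instruments can be handled).  Initial conditions are parametrized at t = 0
(the inoculation time that S0 and X0 refer to); when a replicate's
observations start later, integration still starts at 0.  This makes the
log-likelihood exactly additive when one replicate's observations are split
across several replicate records.  The reference integrator is an adaptive
explicit Runge-Kutta (rtol 1e-8, atol 1e-10); states are clipped at 0
inside the right-hand side because stiff late-depletion steps can
undershoot, and the clip preserves the Monod first integral
X + Y_XS·S to solver tolerance.

## Hierarchical growth model and sampling

The Monod batch-growth experiment is modeled hierarchically: mu_max, Y_XS
and S0 are shared across wells, K_S is fixed at 0.02 g/L (practically
non-identifiable at this data resolution; any small value is numerically
harmless), and each well's inoculum is X0_well = X0_mu · F_offset,well.
Priors: X0_mu ~ Lognormal(log 0.25, 0.1), F_offset ~ Lognormal(0, 0.2)
(the 20% reflects pipetting error at the small 20 µL inoculation volume),
S0 ~ Lognormal(log 20, 0.1), Y_XS ~ Beta(mean 0.6, sd 0.05), mu_max ~
Beta(mean 0.4, sd 0.1).  The Beta priors are moment-matched to shapes
(57, 38) and (9.2, 13.8); their 95% HDIs are [0.5, 0.7] and [0.2, 0.6].

Sampling operates on unconstrained scales — logit for Beta-supported
parameters, log for Lognormal-supported ones — with the Jacobian terms
included, which keeps the history-based proposals effective near bounds.
The DE-MCMC-Z sampler proposes `x' = x + λ(z1−z2) + εη` with z1, z2 two
distinct states from the chain's retained history and η standard normal;
λ defaults to 2.38/√(2d), ε to 1e-4, and at the end of the tuning phase the
first 90% of the accumulated history is dropped, which removes unconverged
burn-in from the proposal pool.  Four chains are run by default (split-R̂
needs several), initialized at the MAP with 1% multiplicative jitter.  The
MAP/MLE themselves come from gradient-free Powell optimization in the
unconstrained space; the MLE variant simply omits prior and Jacobian terms,
whose maximizer then maps to the natural-scale MLE.

Because MCMC needs tens of thousands of posterior evaluations, the
hierarchical model compiles (numba) a specialized log-posterior that
integrates each well with a fixed-step classical Runge-Kutta scheme on the
observation grid (substeps capped at 0.04 h).  This compiled route is
cross-checked in the tests against the generic adaptive-solver objective
(agreement to a fraction of a log-likelihood unit on totals of order 10³)
and is driven by a compiled chain loop; a pure-Python driver handles
arbitrary Python log-posteriors.  R̂ is the rank-normalized split
diagnostic (via arviz); chains that are exactly constant report 1 by
convention.

Posterior predictive sampling pushes posterior draws through the process
model and then draws one response per time point from the calibration
model's predicted distribution, giving bands directly comparable to raw
observations.

## Synthetic data

The generators emulate (a) a glucose assay — asymmetric-logistic trend
(L_L=0.14, L_U=1.90, I_x=8 g/L, S=0.3, c=−1) with Student-t noise
(scale = 0.002 + 0.01·μ, ν=8) on 96 standards log-spaced 0.075–50 g/L;
(b) a biomass/backscatter relation — logistic in log10 CDW (L_L=1.2,
L_U=42, I_x=0.35 decades ≈ 2.2 g/L, S=30 per decade, c=−0.5; scale =
0.3 + 0.015·μ, ν=6) on 48 standards 0.015–15 g/L, whose relative spread
runs from ~20% at low biomass to ~2% at high biomass; and (c) a 28-well
batch-growth experiment at mu_max=0.42 h⁻¹, Y_XS=0.6, S0=20 g/L,
X0_mu=0.25 g/L with lognormal inoculum offsets (sd 0.2), backscatter
sampled every 4 minutes until each well's sacrifice time (spread over
1–15 h), and a single glucose observation at sacrifice.  Trend parameters
were chosen so that both asymptotes are reached inside the standards range;
a calibration design should exceed the range of interest in both
directions, otherwise the curve limits are unidentifiable.

What the generators do *not* emulate: the backscatter overshoot at entry
into stationary phase (a real morphological effect that Monod kinetics
cannot represent), co-substrate effects on the early growth rate, plate
position effects, and drift between calibration sessions.  Passing
recovery tests on this synthetic data therefore demonstrates correctness of
the estimation machinery under the stated model, not robustness to those
real-world misspecifications.

## Problem sizes and known limitations

* Calibration fits use 96 (glucose) and 48 (biomass) standards; the
  recovery tests run at these sizes.
* The end-to-end recovery study runs the full 28-well experiment with
  4 chains × 2,000 tuning + 10,000 draws per seed over 20 seeds, plus a
  single one-seed long run (4 × 20,000 + 60,000) as a convergence
  reference.
* On the 32-dimensional hierarchical posterior the short sampler budget
  above does **not** reach convergence: split-R̂ for the strongly
  correlated pairs (S0 with Y_XS, X0_mu with the offsets) stays well above
  1.01, and the resulting HDIs are narrower than the true posterior, so
  truth-coverage at that budget falls short of nominal.  The long-run
  reference converges (all R̂ ≤ 1.02) and its 90% HDIs cover the
  generating values.  Practical guidance: for this model size use at least
  ~20k tuning and ~10⁵ draws per chain, and always check R̂.
* The HDI search assumes a single contiguous interval; for strongly
  multimodal posteriors the reported HDI is the narrowest single interval,
  not a union of disjoint ones.
* The compiled growth posterior requires the standard experiment layout
  (per-well series on one grid plus one endpoint substrate observation on
  that grid); anything else goes through the generic objective.
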