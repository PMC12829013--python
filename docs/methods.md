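# Methods

`tandemtrack` asks whether two very different ways of tracking the same
birds — dense GPS telemetry and sparse, observer-driven resightings of
coded neckbands — lead to the same conclusions about seasonal migration
and year-round space use. This note records the models, the numerical
choices, and what the synthetic test bed does and does not establish.

## Movement model

Each bird's projected locations are modelled per axis as

    y(t) = m(t) + z(t) + e(t),

where

* `m(t)` is a deterministic periodic mean — an intercept plus `H`
  harmonics (cosine/sine pairs) of a fixed period `P` (default one year,
  365.25 d) — encoding seasonal migration between a breeding and a
  wintering range;
* `z(t)` is a stationary zero-mean Gaussian process from one of three
  families: IID (no autocorrelation), OU (position autocorrelation with
  range-crossing timescale `tau_pos`), or OUF (adds a velocity
  autocorrelation timescale `tau_v < tau_pos`, giving smooth paths);
* `e(t)` is isotropic measurement error.

A single `sigma2` is shared by both axes (isotropy): the outputs of
interest (areas, overlaps) are scalar, and the study's reported variances
are scalar. Anisotropic covariance is out of scope.

### Likelihood

The OU and OUF processes are Markov in a one- or two-dimensional state
(position, or position + velocity), so the exact Gaussian likelihood over
an irregular time grid is evaluated by a Kalman innovations filter with
closed-form transition matrices (no Euler discretisation). The harmonic
mean is profiled out inside every likelihood evaluation: the filter
whitens the data columns and the design columns simultaneously, after
which generalised least squares for the mean coefficients is ordinary
least squares on the whitened columns.

Covariance parameters are estimated by **REML** (the whitened-design
`-1/2 log det(F' Sigma^-1 F)` correction, applied per axis). Plain ML
noticeably underestimates `sigma2` and `tau_pos` at these window lengths
because the seasonal mean is fitted from the same data; with REML, 95%
Wald intervals for `tau_pos` (log scale, curvature-based) cover the
generating value in ~88 of 100 simulated GPS-regime birds. Reported
log-likelihoods and AICc are the plain likelihood at the REML optimum.

Optimisation is L-BFGS-B on log-transformed parameters (`tau_v`
parametrised as a logistic fraction of `tau_pos` so the ordering
constraint is built in), started from variogram-derived values and two
scaled multi-starts (x0.3, x3). If the series carries per-fix error radii
these enter the filter as known variances; otherwise an isotropic error
variance is estimated jointly.

### Model selection

Two-stage, mirroring standard practice for this model class:

1. **Family** by AICc at a reference harmonic count (the smallest positive
   entry of the harmonic grid). `n_eff` is the number of scalar
   observations (2 x fixes; both axes are data). Ties within 1e-6 go to
   the model with fewer parameters. IID acts as the null: selecting it
   means the data cannot resolve autocorrelated movement.
2. **Harmonic count** within the winning family by blocked 10-fold
   cross-validated RMSPE of the trend: covariance parameters stay frozen
   at the full fit, the harmonic mean is re-estimated by GLS on the
   training blocks, and held-out locations are predicted from that trend.
   Predicting from the trend (not the stochastic conditional mean) is
   deliberate: the stochastic interpolation term is common to all harmonic
   counts and would only dilute the contrast between trend models.

### Derived metrics

* **Effective sample size**: `n` for IID, else `T / tau_pos` — the number
  of independent range crossings. Values below 1 flag birds whose range
  cannot be resolved and exclude them from population averages.
* **Periodicity**: `100 * V_m / (V_m + sigma2)`, with `V_m` the
  time-averaged per-axis variance of the harmonic mean (half the sum of
  squared amplitudes, averaged over axes). Measurement error enters
  neither term.
* **Gaussian-equivalent 95% area**: `pi * chi2_{0.95,2} * total variance`,
  where the total per-axis variance includes `V_m` by default (the
  year-round range includes migration); a switch restores the stationary
  variance only.

## Range estimation (aKDE)

Utilisation distributions are weighted Gaussian kernel mixtures over the
observations. The bandwidth is the 2-D Gaussian reference rule with the
*effective* sample size in place of n: `H = sigma2_hat * ess^(-1/3) * I`.
Grid: cell = bandwidth scale / 4, extent = bounding box padded by 4
bandwidth scales (auto-expanding if < 99.99% of the mass is captured,
capped at 600 cells per dimension); every emitted UD is renormalised to
integrate to 1 within 1e-3. The 95% area is the highest-density cell set
holding 95% probability (no contour interpolation), reported in km².

### Debiasing weights

Opportunistic resighting over-samples times and places with many
observers. The debiased estimator minimises the quadratic MISE surrogate
`w'Kw - 2k'w` over the probability simplex, with `K_ij` the fitted
model's positional autocorrelation between observation times and `k_i`
the closed-form mean correlation of observation i with the uniformly
time-averaged sampled window. The time average runs over *sampled blocks*
(gaps > 90 d split the window), so seasonal subsets of multi-year
deployments are averaged over the seasons actually observed rather than
the empty months between them. The QP is solved exactly by a primal
active-set method on the KKT system (duality gap <= 1e-10), deterministic
from uniform weights.

Behaviour worth knowing: for regular sampling the interior weights are
exactly uniform, while the first/last observations are down-weighted
(half their correlation window lies outside the track) — a boundary
effect, not a defect; bursts of temporally clustered observations share a
single observation's worth of weight. The contrast between the debiased
and non-debiased UD of the same bird (a Bhattacharyya coefficient,
"self-debias overlap") is the package's proxy for sampling bias: ~1.0 for
unbiased regular GPS sampling, measurably lower when sightings follow an
effort hotspot.

## Overlap design

The Bhattacharyya coefficient `sum sqrt(p q) * cell_area` is computed
after bilinear resampling of both UDs to a common grid (union extent,
finer cell size) and renormalisation; it is accurate to ~1% of the
Gaussian closed form `exp(-d^2 / 8 s^2)` on Gaussian fixtures. Pairs are
formed within capture sites only, classified GPS-GPS / NB-NB / GPS-NB,
with the pair effective sample size taken as the min of the two UD
degrees of freedom (threshold >= 1 by default). Seasons are summer =
May-Jul, winter = Nov-Jan; seasonal models use a stationary mean. Group
summaries of bounded quantities (overlap, periodicity) are computed on
the logit scale.

## Population means and sample size

Per-bird estimates are pooled with a random-effects Gaussian model on a
transformed scale (log for timescales and areas, logit for percentages):
`value_i ~ Normal(mu, s^2 + v_i)`, with `v_i` the bird's sampling
variance from the fit's observed information (chi-square fallback
`2/ess` when the curvature is unusable) and `(mu, s^2)` by maximum
likelihood (bounded scalar search on the profile likelihood of `s^2`).
Intervals (50/75/95%) are normal-approximation intervals for `mu`,
back-transformed; the back-transformed mean is therefore a median-type
population value. This random-effects construction is this package's own
documented surrogate for hierarchical population averaging of
non-stationary movement models; it is not a re-derivation of any specific
published estimator.

The leave-out-k analysis subsamples k of N birds (without replacement,
100 replicates per k, deterministic per-(group, k, replicate) streams
from one root seed), recomputes the mean Gaussian area with the same
random-effects routine, and records the percent deviation from the
all-bird mean; the minimum adequate sample size is the smallest k whose
median absolute deviation falls below 10%.

## Synthetic data generator

The generator is first-class, tested code; it defines the conditions
under which every downstream claim is verified.

* **Trajectories**: OUF deviations about the periodic seasonal loop,
  simulated exactly via the linear-Gaussian state transition at an
  internal step of `min(tau_v/5, 6 h)`. Defaults: `tau_pos` 12 d, `tau_v`
  0.3 d, per-axis sigma 40 km (median), 630-day deployments, a 1200 km
  breeding-wintering loop with two harmonics (skew term 0.25 for
  asymmetric residence), anchored mid-June/mid-December. Per-bird
  lognormal heterogeneity in range size (log-sd 0.6) and migration
  distance (log-sd 0.25) reproduces the wide spread of individual range
  areas and the short-stopping variability seen in wild populations.
* **GPS channel**: daily scheduled fixes, 5% independent dropout, 15 m
  isotropic error — about 600 retained fixes per bird.
* **Resight channel**: an inhomogeneous Poisson process thinned by a
  Gaussian-mixture observer-effort surface; per-bird lognormal reporting
  rates (median 0.55 sightings/bird-month, log-sd 0.9) give roughly 0-70
  sightings per bird with a median near 10, matching the shape of real
  neckband reporting.
* **Pairs**: a configurable fraction of birds are mated pairs sharing one
  trajectory with independent observation noise.

Everything is bit-reproducible from the configuration seed
(`SeedSequence` spawning, one stream per trajectory).

**What the generator does not emulate**: behavioural state switching,
daily (roost-forage) periodicity, habitat selection, mortality and tag
failure, observer phenology (weekends, holidays), misread neckband codes.
Passing tests therefore show that the pipeline recovers what this model
family can represent under realistic sampling — not that real goose data
are free of the unmodelled structure (the scale mismatch between daily
GPS and sparse resights, which the pipeline reproduces, is exactly such a
structural effect).

## Problem sizes

The test suite and the acceptance script run simulation studies at desk
scale, chosen so each claim is measured with adequate Monte-Carlo
precision: 100 birds for interval coverage, 20 seeded populations for the
method-concordance test, a 50-bird dual-channel population (20 GPS / 30
neckband) for the end-to-end study. Larger populations change none of the
qualitative conclusions, only the interval widths.

## Known limitations

* Wald intervals on log-parameters still undercover slightly (~88% at
  nominal 95%) for short deployments; profile-likelihood intervals would
  be better and slower.
* The annual Gaussian-equivalent area and the aKDE highest-density area
  answer different questions for strongly migratory birds (the former
  covers the whole loop ellipse, the latter the occupied ranges); both
  are reported.
* Bhattacharyya values are grid-quantised at about the 0.01 level; the
  common-grid resampling is bilinear, not mass-conserving, and relies on
  renormalisation.
* The IID family confounds process variance and measurement error; its
  `sigma2` is the sum.
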