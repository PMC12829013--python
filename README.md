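# tandemtrack

Do sparse, observer-driven resightings of marked birds tell the same
story about year-round movements as dense GPS telemetry?

Management of migratory waterbirds (greylag geese are the motivating
system) has historically relied on capture-mark-resight (CMR) data:
thousands of birds carry coded neckbands, and volunteers report where and
when they see them. Modern studies instead deploy GPS collars on far
fewer birds at far higher temporal resolution. `tandemtrack` implements a
statistical pipeline for comparing the two channels head-to-head — and a
synthetic dual-observation generator so every stage can be validated
against known ground truth.

## What it computes

For each bird (either channel) the pipeline fits a continuous-time
movement model with a seasonal mean,

    y(t) = m(t) + z(t) + error,     m(t) = intercept + Σ_h [a_h cos(2πht/P) + b_h sin(2πht/P)],

where `z(t)` is IID, OU, or OUF: the OU family carries the position
autocorrelation timescale τ_pos (range-crossing time), OUF adds the
velocity timescale τ_v (behavioural persistence), and the harmonics of
the one-year period P encode migration. Likelihoods are exact (Kalman
innovations filter on the irregular time grid, harmonic mean profiled by
GLS, REML for the variance parameters); AICc ranks the autocorrelation
families and blocked cross-validated RMSPE ranks the harmonic counts.

Downstream of the fits:

* **aKDE ranges** — autocorrelated kernel density home ranges whose
  bandwidth uses the effective sample size `T/τ_pos` instead of n, with
  optional MISE-optimal debiasing weights that down-weight temporally
  clustered (over-reported) observations; 95% areas in km².
* **Overlap designs** — Bhattacharyya coefficients `∫√(p q)` between all
  same-site pairs of UDs, classified GPS-GPS / NB-NB / GPS-NB, per season
  (summer = May–Jul, winter = Nov–Jan); plus the self debias-contrast
  (debiased vs non-debiased UD of the same bird) as a sampling-bias proxy.
* **Population means** — random-effects meta-analysis of τ_pos, τ_v,
  periodicity, and range area per capture site and tracking method, with
  50/75/95% intervals.
* **Sample-size analysis** — leave-out-k subsampling: the smallest number
  of birds for which the median |deviation| of the subsample mean area
  from the all-bird mean falls below 10%.

Preprocessing implements the field-standard screens: juvenile censoring
to April 01 of the second spring, mated-pair censoring (keep the longer
tracking record), one sighting per bird-day, a mean ground-speed
plausibility screen (3.65 m/s ≈ 315 km/day), an iterative 40 m/s GPS
speed filter, and thinning of GPS fixes to the one closest to local solar
noon each day. All analysis runs in a single oblique Lambert azimuthal
equal-area frame (authalic-sphere formulation) so variances are in m² and
areas in km²; geodesic distances are Vincenty/WGS84.

## Worked example

Simulate a 12-bird population observed through both channels, fit each
bird, and pool per method:

```python
from tandemtrack.synthetic_data import SimulationConfig, make_population
from tandemtrack.ctmm_core import fit_ctmm, periodicity
from tandemtrack.population_meta import select_contributors, parameter_tables

cfg = SimulationConfig(seed=1, n_individuals=12)
meta, series, truth = make_population(cfg)
models = [fit_ctmm(s, harmonic_grid=(0, 1, 2))[0] for s in series if len(s) >= 5]

by_id = {m.individual_id: m.method for m in meta}
for m in models[:4]:
    print(f"{m.individual_id}  {by_id[m.individual_id]:8s} {m.family}  "
          f"tau_pos={m.tau_pos/86400:6.2f} d  ess={m.ess_area:6.1f}  "
          f"periodicity={periodicity(m):5.1f}%")

sel = select_contributors(models)      # drop IID fits and ess < 1
groups = [by_id[m.individual_id] for m in sel]
for est in parameter_tables(sel, groups):
    print(f"{est.group:9s} {est.parameter:16s} mean={est.mean:12.3f} "
          f"95% CI=({est.ci95[0]:.3f}, {est.ci95[1]:.3f})  n={est.n_contributing}")
```

prints

```
N000  gps      OUF  tau_pos= 11.05 d  ess=  57.0  periodicity= 99.1%
N001  neckband OUF  tau_pos=  7.71 d  ess=  71.6  periodicity= 99.4%
N002  neckband OUF  tau_pos= 15.82 d  ess=  34.7  periodicity= 94.9%
N003  gps      OUF  tau_pos= 10.54 d  ess=  59.8  periodicity= 94.6%
gps       tau_pos_d        mean=      10.703 95% CI=(9.270, 12.359)  n=6
gps       tau_v_d          mean=       0.326 95% CI=(0.263, 0.405)  n=6
gps       periodicity_pct  mean=      98.713 95% CI=(97.560, 99.325)  n=6
gps       area_km2         mean= 1818901.077 95% CI=(1336558.121, 2475314.075)  n=6
neckband  tau_pos_d        mean=      10.768 95% CI=(6.749, 17.180)  n=5
neckband  tau_v_d          mean=       0.393 95% CI=(0.094, 1.641)  n=2
neckband  periodicity_pct  mean=      98.317 95% CI=(96.727, 99.142)  n=5
neckband  area_km2         mean= 2281986.711 95% CI=(1729011.507, 3011815.323)  n=5
```

The generating values were τ_pos = 12 d and τ_v = 0.3 d. Both channels
recover them; the neckband intervals are wider (9 sightings median vs
~600 GPS fixes), τ_v is estimable for only 2 of 5 neckband birds, and the
mean range areas of the two methods agree within their intervals — the
pattern the pipeline is designed to quantify.

A command-line interface wraps the same functions
(`tandemtrack simulate | preprocess | fit | akde | overlap | meta |
samplesize | convert`); see `tandemtrack --help`.

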