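# Methods

This note documents the models, the synthetic-data generators and the
numerical choices behind `larvamatch`, and what the passing test suite does
and does not demonstrate about real data.

## Idealized ocean

The ocean surrogate is two-dimensional (a single surface layer): the
vertical distribution of eggs and larvae is collapsed because only the
horizontal transport signal feeds the downstream analysis. The coastline is
a straight meridian at x = 0 with land at x < 0, so "northward along the
coast" (+y) and "offshore" (+x) are unambiguous. The grid is 31 × 200 cells
of 10 km (one land column), 184 daily fields spanning 1 March – 31 August.
Daily temporal resolution matches the daily drift output the analysis
consumes.

The velocity field has three parts:

- **Coastal jet** — v = U · [f + (1 − f) e^(−x/L)], with peak speed
  U = 8 km/day, decay scale L = 50 km, and an offshore floor f = 0.25.
  The floor plays two roles: far-offshore water still moves north (as the
  offshore branch of a real slope current does), and it guarantees
  v ≥ 0 off land whenever the eddy amplitude does not exceed f·U.
- **Eddies** — a divergence-free perturbation u′ = −∂ψ/∂y, v′ = +∂ψ/∂x from
  a smoothed random streamfunction (Gaussian kernel, 60 km correlation
  length), computed with the same central-difference operators used in the
  package's divergence diagnostic, so the discrete divergence vanishes to
  machine precision. The streamfunction rotates between two random phases
  with a 15-day period. This matters: a frozen eddy field traps particles
  on closed streamlines and slow filaments, making Lagrangian travel times
  both slower than the Eulerian mean and strongly seed-dependent; a
  rotating field restores mixing, and scenario timing becomes reproducible
  across seeds. Peak perturbation speed is normalized to 2 km/day.
- **Wave pulse** — a transient alongshore enhancement with a cos² time
  envelope, confined south of 1750 km (50 km south of the colony box) so it
  sweeps southern larvae *toward* the box without blasting the northern
  stream out of it. Maximum total speed is bounded by
  jet + pulse amplitude + 3 × eddy amplitude.

SST = 4 °C + 0.04 °C/day seasonal ramp + a 3 °C southern warm anomaly
decaying linearly northward. The gradient is the mechanism that makes
southern-origin larvae grow larger; the ramp gives the within-season
warming that prey influx rides on.

### Scenario presets

Scenario timing is expressed through one calibrated constant,
`PULSE_ARRIVAL_LAG` = 26 days: the interval between the velocity-pulse
center and the peak of the resulting in-box southern abundance (particles
swept by the pulse still need to cover the remaining distance and
accumulate). The calibration was done once on the default geometry; with
it, the matched preset peaks in the box on day 112–113 against a mean
hatch day of 113.

- `matched_wave`: amplitude 45 km/day, half-width 22 days, centered so the
  in-box peak lands on the mean hatch date (±3 days).
- `late_wave`: the identical pulse shifted +25 days.
- `flat_south`: a weak (12 km/day), very broad (half-width 60 days)
  enhancement producing a low, gradually increasing southern influx through
  the season and no coherent wave.

The pulse is strong and long deliberately: the band of southern particles
spans ~600 km when the wave starts, and only a cumulative displacement
exceeding that width compresses the band into a coherent arrival wave; a
weaker pulse merely advances a smeared trickle.

## Drift model

Releases: 300 particles per ground per release day, days 0, 3, …, 60
(1 March – 30 April inclusive — the only 3-day schedule consistent with a
69,300 total over 11 grounds and 21 dates), initialized as eggs with a
2 km point-release jitter. Grounds sit 25 km offshore at alongshore
distances of 300–1750 km south of the box center, increasing with ground
id; ids 1–2 are "northern", 4–11 "southern", ground 3 neither.

Integration: daily fields held constant within a day; Euler (default) or
midpoint-RK2 with a timestep that must divide one day evenly. Positions are
continuous km; daily snapshots are taken at 00:00 regardless of sub-daily
stepping. Box membership uses closed intervals on both edges.

Boundaries: a particle stepping onto land has the onshore displacement
cancelled (`hold`, default; `reflect` optional) — chosen as the simplest
policy that preserves count conservation. Particles crossing an open
boundary are clamped to it and flagged; they remain in the bookkeeping
(conservation is an invariant, tested daily).

Growth: eggs have no mass dynamics; at age = 21 days a particle becomes a
larva with mass 0.3 mg (an arbitrary but documented constant — only the
southern/northern mass *ratio* matters downstream) and thereafter grows
exponentially at g_ref = 0.016/day (at T_ref = 5 °C) with Q10 = 2. With the
default SST field these values make in-box southern larvae ~2–2.5× heavier
than northern ones during the season, the size ordering reported for the
real system; the growth law itself is a modeling choice, since only the
warm-water-drift mechanism, not an equation, is specified by the source
analyses.

## Exposure covariates

Daily per-ground counts inside the box count **larvae only** by default
(eggs are not guillemot prey); an `include_eggs` switch exists. Box SST is
the mean over grid cells inside the box, then averaged over the 7-day
window. Southern + northern + ground-3 counts partition the total every
day (tested). Trailing windows cover exactly anchor−6 … anchor and refuse
incomplete coverage. Raw and within-year standardized covariates are both
emitted; biomass is mean mass × abundance index.

## CORT preparation

Concentrations below the 1.21 ng/mL assay detection limit are assigned the
limit value (as in the source assay protocol) and flagged; flooring is
idempotent and a second floor+log pass is refused via the presence of the
`log10_cort` column. Missing CORT rows and rows whose capture day lacks a
complete exposure window are flagged and excluded from fits with a logged
count, never silently dropped. Phase is the design label (early = at
hatching, late ≈ 15 days posthatch), not the realized recapture lag.

## Inference

Mixed models are fitted with statsmodels' MixedLM. ML is used for all AIC
comparisons and LRTs; REML only for reporting final-model variance
components. The optimizer order is BFGS, then CG, then Powell: L-BFGS in
this setting occasionally reports convergence at a poor optimum, which
inflates likelihood-ratio statistics; with BFGS the null rejection rate of
the LRT sits at its nominal 5% (tested against the binomial envelope at
500 null replicates).

AIC = −2·loglik + 2·k with k counting fixed coefficients **plus both
variance parameters** — documented because the ≥2-unit selection rule
depends on the convention. The selection rule: the lowest-AIC model wins
only if it is ≥2 units below every nested simpler candidate; otherwise the
selection falls back to the simplest model within 2 units of the minimum
(ties broken by lower AIC). Nesting is derived from fixed-term sets.

Year enters the reference model numerically, coded 0/1/2 (first study
year = 0). This is the only coding under which a main slope of −1.269 with
interaction +1.140 reproduces the reported first-year within-year slope
(−1.24): with 1/2/3 coding the implied first-year slope would be −0.129,
contradicting the per-year fits. Factor coding (treatment contrasts, first
level reference) is available for year-effect models elsewhere.

Subgroup reports fit each (overall / sex / phase) × year subset separately,
retaining terms by backward likelihood-ratio elimination at P < 0.1, with
the +, *, **, *** marker scheme. Subsets smaller than 10 rows or 3 pairs
are reported as unfit rather than dropped.

## Synthetic CORT generator

The generator reproduces the repeated-measures design: two birds per pair,
two phases per bird, pairs followed 1–3 years (55 pairs, 86 pair-years,
344 observations in the reference design; the year layout keeps the three
years within a few pair-years of balance, mirroring the reported cell
sizes). Both pair members share capture days. log10 CORT = linear predictor
+ pair intercept + residual, with the reference fixed effects as defaults
and ICC 0.18. Back-transformed values below the detection limit are floored
so the generator exercises the ingestion rule (~1.5% of samples under
defaults).

Two calibrations were fixed once, before any recovery experiment was run,
and document scale choices the printed tables leave open:

- **Total variance 0.09** (SD 0.3 on the log10 scale). The per-cell "±"
  values of the reference summaries (0.04–0.07 at n ≈ 30) are implausibly
  small as ng/mL standard errors; treating them as log10-scale standard
  errors implies a cell SD near 0.3. A total variance of 1 on the log10
  scale would imply 10-fold CORT swings within cells, which no summary
  supports.
- **Within-year covariate SD 0.15** for `larvae_S`. The reference slope
  −1.269 ± 0.263 at N = 344 pins the product of covariate SD and effective
  sample size; SD ≈ 0.15 reproduces a standard error of that order and
  keeps detection-limit flooring rare. Unit-SD standardization would make
  the printed coefficients imply ~100-fold CORT ranges and mass flooring.
  The covariate is drawn either from a lognormal surrogate or from the
  actual drift+exposure pipeline (centered within year and scaled to the
  same SD), so the full chain can be exercised.

The intercept (1.73) puts median CORT near 6 ng/mL, inside the reported
4–8.5 ng/mL range of cell means.

The chick generator draws per-year hatch dates, day-15 masses, growth
rates, tarsus lengths (SDs reconstructed from the printed SEs and Ns) and
Bernoulli survival at the printed per-year probabilities for the printed
brood counts (36/39/33).

## Parameter recovery

`scripts/acceptance.py` (and the corresponding acceptance tests) run 200
replicates of simulate → fit at the reference design and average the
estimates. Recovered means sit within Monte-Carlo noise of the generating
values (replicate SD ≈ 0.17 for the southern-larvae slope, so the standard
error of the 200-replicate mean is ≈ 0.012); the ML variance share
averages ≈ 17.2% against a generating 18% — the familiar small downward
bias of ML variance components at 55 groups.

## Problem sizes

The test suite runs reduced problem sizes chosen to preserve the behavior
under test: drift-based checks use 50 particles per release (11,550 total)
rather than 300 — arrival timing and composition are release-rate
invariant — while release arithmetic and the worked example use the full
69,300. The LRT calibration uses 500 null replicates of 200 observations
from 50 pairs: calibration improves with size, and at this size the
asymptotic χ² reference is accurate (at ~80 observations the test is
measurably liberal, ~7.5% at nominal 5%).

## What passing tests do and do not show

The generators share their structural assumptions with the fitted models:
Gaussian pair effects and residuals, a log-linear covariate effect, an
idealized coastline with stationary statistics, no larval mortality or
behavior, no assay plate structure. Recovery and calibration results
therefore validate the *implementation* (estimators recover what generated
the data; selection and test procedures behave nominally), not the
*adequacy* of those assumptions for real field data. Real ocean hindcasts,
real coastline geometry, vertical larval behavior, and prey-field feedbacks
are all outside what these tests can speak to.

## Known limitations

- The 2-D ocean surrogate cannot represent vertical shear dispersal; the
  wave-pulse mechanism is a kinematic stand-in for whatever synoptic
  variability bunches southern larvae in reality.
- Larval "abundance" is a particle count per box, not an absolute density;
  between-year totals are constant by design.
- Floored CORT values enter fits at the limit value (as in the source
  protocol) rather than through a censored likelihood; at the default ~1.5%
  flooring rate the induced bias is negligible, but the generator can
  produce regimes where it would not be.
- Chick outcome models treat one chick per brood and ignore within-season
  brood structure beyond the pair random effect.
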