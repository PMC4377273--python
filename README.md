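# larvamatch

A desk-scale pipeline coupling a Lagrangian cod-larva drift simulation to a
mixed-effects analysis of baseline corticosterone (CORT) in breeding common
guillemots (*Uria aalge*), built to study the match–mismatch question: does
the short-term availability of 0-group cod prey around a colony, set by when
waves of southern-spawned larvae drift past, explain day-to-day variation in
the adults' physiological stress?

It is written for quantitative ecologists who want to exercise and validate
every stage of such an analysis — ocean forcing, particle drift, prey
exposure covariates, hormone data preparation, mixed-model selection, and
chick outcomes — without any external ocean archive or field data: each
stage has a synthetic generator whose defaults encode the study conditions,
so the whole chain is testable end to end, including parameter recovery at
the published design.

## The model

**Drift.** Eggs are released as particles (300 per ground every third day
through March–April from 11 spawning grounds ordered north → south; 69,300
in total), develop into larvae after a fixed 21-day egg stage, and are
advected through gridded daily velocity fields by bilinear interpolation
(Euler or midpoint-RK2, sub-daily steps). Larval mass grows as

```
dm/dt = g_ref · Q10^((T − T_ref)/10) · m
```

at the local interpolated SST, so southern-origin larvae — which drift
longer through warmer water — arrive larger. No particle is ever removed;
the daily particle count equals the cumulative releases, isolating drift
pattern variability from stock size.

**Exposure.** Larvae are counted daily inside a 100 × 100 km colony box
(the adult foraging range). `larvae_S` is the sum over southern grounds
4–11, `larvae_N` over northern grounds 1–2 (ground 3 belongs to neither
aggregate). Each CORT sample is joined to the trailing 7-day window — the 7
days up to and including the capture day — of summed larval counts and mean
box SST.

**Inference.** log10-transformed CORT (floored at the 1.21 ng/mL assay
detection limit) is modelled with linear mixed models using breeding pair
as a random intercept:

```
log10 CORT ~ time + year + larvae_S + year:larvae_S + (1 | pair)
```

with year coded numerically (0, 1, 2). Models are compared by AIC with the
rule that the best model must lie at least 2 units below every nested
simpler model; covariate probabilities come from likelihood-ratio tests.
The pair intercept's variance share is the ICC σ²_pair / (σ²_pair + σ²_res).

**Scenarios.** Three ocean presets reproduce the qualitative structure of
three study years: `matched_wave` (an episodic wave of southern larvae
peaking in the box during the hatching period), `late_wave` (the same wave
25 days later), and `flat_south` (a weak, gradual southern influx).

## Worked example

```python
import numpy as np
import larvamatch as lm

preset = lm.scenario_preset("matched_wave", seed=1)
fields = lm.make_coastal_fields(lm.GridSpec(), preset.ocean)
schedule = lm.ReleaseSchedule()          # 300 eggs / ground / 3 days
history = lm.run_simulation(fields, schedule, lm.default_grounds(), lm.DriftConfig())
abund = lm.daily_abundance(history, lm.ColonyBox(), fields)

win = lm.trailing_window(abund, anchor_day=lm.MEAN_HATCH_DAY)
peak_day = int(abund.loc[abund["southern"].idxmax(), "day"])
print(f"particles released: {history.n_particles}")
print(f"southern in-box peak: day {peak_day} (mean hatch day {lm.MEAN_HATCH_DAY})")
print(f"7-day exposure at hatch: larvae_S={win.larvae_S:.0f}, larvae_N={win.larvae_N:.0f}, "
      f"SST={win.sst_mean:.1f} C")
```

prints

```
particles released: 69300
southern in-box peak: day 112 (mean hatch day 113)
7-day exposure at hatch: larvae_S=149899, larvae_N=9825, SST=8.6 C
```

— the matched scenario delivers its southern wave into the foraging box
within a day of the mean hatch date (day indices count from 1 March), and
the hatch-day prey window is dominated by southern larvae. In-box southern
larvae average ~2.4× the mass of northern ones over the season, the size
advantage that makes them the energetically preferred prey.

The full pipeline — three scenario years, synthetic birds generated from
the actual drift-derived exposures, ingestion, model selection tables,
chick outcomes, and a manifest — runs from one command:

```bash
larvamatch all --seed 42 --out runs/demo
```

Input CSV schemas: bird samples carry
`pair_id, bird_id, sex, year, phase, capture_day, cort` (ng/mL); chick
records carry `chick_id, pair_id, year, hatch_day_june, age_first,
age_second, mass_first, mass_second, tarsus, survived_to_15`.

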