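"""Synthetic bird and chick data with the statistical structure the
analysis assumes, for full parameter-recovery testing without field data.

The CORT generator reproduces the repeated-measures design of the field
study -- two birds per breeding pair, two capture phases per bird (early,
at hatching, and late, ~15 days posthatch), pairs followed for one to
three study years, 55 pairs and 344 observations in the reference design
-- and draws log10 CORT from the fitted-model structure: a linear
predictor in time, numeric year, the southern-larvae covariate and its
year interaction, plus a pair random intercept carrying 18% of the total
variance.  Back-transformed concentrations below the 1.21 ng/mL assay
detection limit are floored, so the generator exercises the
detection-limit rule.

Reference fixed-effect defaults (log10 scale): time +0.246, year -0.539,
larvae_S -1.269, year x larvae_S +1.140.  Year is coded numerically as
0/1/2 (first study year = 0): with that coding the within-first-year
southern-larvae slope equals the main effect, which is the only coding
consistent with the per-year estimates the reference analysis reports.

The chick generator draws per-year hatch dates, day-15 masses, growth
rates, tarsus lengths and Bernoulli survival from the study's per-year
means, standard errors and sample sizes (36, 39, 33 broods).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cort import DETECTION_LIMIT
from .ocean import MEAN_HATCH_DAY

__all__ = [
    "GenParams",
    "ChickGenParams",
    "simulate_design",
    "simulate_cort",
    "simulate_chicks",
]


@dataclass(frozen=True)
class GenParams:
    """Generating parameters of the synthetic CORT model.

    ``sigma2_total`` is the total (pair + residual) variance on the log10
    scale; 0.09 (SD 0.3) makes simulated per-cell standard errors match
    the 0.04-0.07 magnitude of the reference per-cell summaries at n ~ 30.
    ``covariate_sd`` is the within-year SD of the larvae_S covariate; 0.15
    keeps the implied effect sizes and the rate of detection-limit
    flooring (~1-2% of samples) realistic.  ``intercept`` puts median CORT
    near 6 ng/mL.
    """

    intercept: float = 1.73
    beta_time: float = 0.246
    beta_year: float = -0.539
    beta_larvae_s: float = -1.269
    beta_interaction: float = 1.140
    icc: float = 0.18
    sigma2_total: float = 0.09
    n_pairs: int = 55
    n_obs: int = 344
    covariate_sd: float = 0.15
    mean_hatch_day: int = MEAN_HATCH_DAY
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1); the boundary icc=1 is disallowed")
        if self.n_obs < self.n_pairs:
            raise ValueError("n_obs must be >= n_pairs")
        if self.n_obs % 4 != 0:
            raise ValueError("n_obs must be a multiple of 4 (2 birds x 2 phases)")
        for name in ("intercept", "beta_time", "beta_year", "beta_larvae_s",
                     "beta_interaction", "sigma2_total", "covariate_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _pair_year_layout(n_pairs: int, n_pair_years: int) -> list[tuple[int, int]]:
    """Assign study years (1..3) to pairs: every pair gets one year first,
    then additional pair-years are dealt out round-robin with a different
    year each time, mirroring the mix of one-, two- and three-season
    families while keeping the three years roughly balanced."""
    if n_pair_years > 3 * n_pairs:
        raise ValueError("cannot place more than 3 seasons per pair")
    layout: list[tuple[int, int]] = []
    for k in range(n_pair_years):
        pair = k % n_pairs
        season_rank = k // n_pairs  # 0 = first season for this pair, ...
        year = (pair + season_rank) % 3 + 1
        layout.append((pair, year))
    return layout


def simulate_design(
    params: GenParams,
    rng: np.random.Generator | None = None,
    exposure: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the covariate table of the repeated-measures design.

    Each pair-year contributes 4 rows (female and male, early and late
    phase).  Capture days are drawn around a pair-level hatch date (early)
    and 15 days later (late).  The larvae_S covariate is taken from an
    exposure table (columns ``year``(optional), ``day``, ``larvae_S``,
    ``larvae_N``, ``sst``) when given -- exercising the actual drift +
    exposure chain -- otherwise from a lognormal surrogate; either way it
    is standardized within year (mean 0) and scaled to ``covariate_sd``.
    Deterministic for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_pair_years = params.n_obs // 4
    layout = _pair_year_layout(params.n_pairs, n_pair_years)

    rows = []
    for pair, year in layout:
        hatch = params.mean_hatch_day + rng.normal(0.0, 3.0)
        early_day = int(round(hatch + rng.normal(0.0, 1.5)))
        late_day = early_day + 15
        for sex in ("F", "M"):
            for phase, day in (("early", early_day), ("late", late_day)):
                rows.append({
                    "pair_id": f"p{pair:03d}",
                    "bird_id": f"p{pair:03d}{sex}",
                    "sex": sex,
                    "year": year,
                    "year_num": year - 1,
                    "phase": phase,
                    "time": 0 if phase == "early" else 1,
                    "capture_day": day,
                })
    design = pd.DataFrame(rows)

    if exposure is not None:
        keys = ["year", "capture_day"] if "year" in exposure.columns else ["capture_day"]
        exp = exposure.rename(columns={"day": "capture_day"})
        design = design.merge(exp, on=keys, how="left", validate="many_to_one")
        if design["larvae_S"].isna().any():
            missing = design.loc[design["larvae_S"].isna(), "capture_day"].unique()
            raise ValueError(f"exposure table lacks windows for capture days {missing}")
        raw_s = design["larvae_S"].to_numpy(dtype=float)
        raw_n = design.get("larvae_N", pd.Series(np.zeros(len(design)))).to_numpy(dtype=float)
        sst = design.get("sst", pd.Series(np.zeros(len(design)))).to_numpy(dtype=float)
    else:
        # lognormal surrogate for the windowed southern-larvae counts; one
        # draw per pair-year-phase (both pair members share capture days)
        key = design[["pair_id", "year", "phase"]].apply(tuple, axis=1)
        uniq = {k: rng.lognormal(0.0, 0.8) for k in dict.fromkeys(key)}
        raw_s = np.array([uniq[k] for k in key])
        uniq_n = {k: rng.lognormal(1.0, 0.5) for k in dict.fromkeys(key)}
        raw_n = np.array([uniq_n[k] for k in key])
        sst = 6.0 + 0.03 * (design["capture_day"].to_numpy() - 100) + rng.normal(0, 0.3, len(design))

    for name, raw in (("larvae_S", raw_s), ("larvae_N", raw_n)):
        z = np.empty_like(raw, dtype=float)
        for year in design["year"].unique():
            m = design["year"].to_numpy() == year
            sd = raw[m].std()
            z[m] = (raw[m] - raw[m].mean()) / sd * params.covariate_sd if sd > 0 else 0.0
        design[name] = z
        design[name + "_raw"] = raw
    design["sst"] = sst
    return design


def simulate_cort(
    design: pd.DataFrame,
    params: GenParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw CORT observations from the generating mixed model.

    log10 CORT = intercept + beta_time*time + beta_year*year_num
    + beta_larvae_s*larvae_S + beta_interaction*year_num*larvae_S
    + pair intercept ~ N(0, icc*sigma2) + residual ~ N(0, (1-icc)*sigma2);
    concentrations are back-transformed to ng/mL and floored at the
    detection limit, and ``log10_cort`` is recomputed from the floored
    value -- exactly what the ingestion stage would produce.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    out = design.copy()
    pairs = out["pair_id"].unique()
    sd_pair = np.sqrt(params.icc * params.sigma2_total)
    sd_resid = np.sqrt((1.0 - params.icc) * params.sigma2_total)
    pair_eff = dict(zip(pairs, rng.normal(0.0, sd_pair, size=pairs.size)))

    lin = (
        params.intercept
        + params.beta_time * out["time"].to_numpy(dtype=float)
        + params.beta_year * out["year_num"].to_numpy(dtype=float)
        + params.beta_larvae_s * out["larvae_S"].to_numpy(dtype=float)
        + params.beta_interaction * out["year_num"].to_numpy(dtype=float) * out["larvae_S"].to_numpy(dtype=float)
    )
    eta = lin + out["pair_id"].map(pair_eff).to_numpy() + rng.normal(0.0, sd_resid, len(out))
    cort_raw = 10.0 ** eta
    floored = np.maximum(cort_raw, DETECTION_LIMIT)
    out["linear_predictor"] = lin
    out["cort_raw"] = cort_raw  # pre-floor concentration, for ingestion tests
    out["cort"] = floored
    out["cort_floored"] = cort_raw < DETECTION_LIMIT
    out["log10_cort"] = np.log10(floored)
    return out


#: Per-year reference values behind the chick generator: means +/- SE (N)
#: of hatch date (day in June), day-15 body mass (g), growth (g/day) and
#: tarsus (mm), plus survival proportions of the 36/39/33 followed broods.
@dataclass(frozen=True)
class ChickGenParams:
    n_broods: tuple[int, int, int] = (36, 39, 33)
    survival: tuple[float, float, float] = (0.89, 0.87, 0.82)
    hatch_mean: tuple[float, float, float] = (24.3, 21.5, 21.1)
    hatch_se: tuple[float, float, float] = (0.5, 0.6, 0.6)
    mass_mean: tuple[float, float, float] = (192.7, 240.2, 236.5)
    mass_se: tuple[float, float, float] = (5.1, 6.5, 7.1)
    growth_mean: tuple[float, float, float] = (6.6, 10.6, 11.0)
    growth_se: tuple[float, float, float] = (0.6, 0.9, 0.9)
    tarsus_mean: tuple[float, float, float] = (38.7, 39.9, 40.1)
    tarsus_se: tuple[float, float, float] = (0.3, 0.4, 0.5)
    n_measured: tuple[int, int, int] = (32, 34, 27)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.survival):
            raise ValueError("survival probabilities must lie in [0, 1]")


def simulate_chicks(
    params: ChickGenParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one chick per followed brood for each of the three years.

    Per-chick draws: hatch date, survival to day 15 (Bernoulli at the
    year's probability), and for survivors the first-capture (age 3 +/- 2
    days) and second-capture (age 15 +/- 1 days) masses consistent with
    the year's growth-rate distribution, plus tarsus length.  Standard
    deviations are reconstructed from the per-year SEs and measured Ns.
    """
    if params is None:
        params = ChickGenParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rows = []
    cid = 0
    for yi in range(3):
        year = yi + 1
        n = params.n_broods[yi]
        sd = lambda se, nm: se * np.sqrt(nm)
        nm = params.n_measured[yi]
        for _ in range(n):
            hatch = rng.normal(params.hatch_mean[yi], sd(params.hatch_se[yi], n))
            survived = bool(rng.uniform() < params.survival[yi])
            age1 = int(np.clip(round(rng.normal(3, 1)), 1, 5))
            age2 = int(np.clip(round(rng.normal(15, 0.5)), 14, 16))
            growth = rng.normal(params.growth_mean[yi], sd(params.growth_se[yi], nm))
            mass2 = rng.normal(params.mass_mean[yi], sd(params.mass_se[yi], nm))
            tarsus = rng.normal(params.tarsus_mean[yi], sd(params.tarsus_se[yi], nm))
            mass1 = mass2 - growth * (age2 - age1)
            rows.append({
                "chick_id": f"c{cid:03d}",
                "pair_id": f"p{cid % 60:03d}",
                "year": year,
                "hatch_day_june": round(float(hatch), 1),
                "age_first": age1,
                "age_second": age2 if survived else np.nan,
                "mass_first": round(float(max(mass1, 40.0)), 1),
                "mass_second": round(float(mass2), 1) if survived else np.nan,
                "tarsus": round(float(tarsus), 1) if survived else np.nan,
                "survived_to_15": survived,
            })
            cid += 1
    return pd.DataFrame(rows)
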