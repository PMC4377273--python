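"""Chick outcome statistics: growth, day-15 mass, tarsus, survival.

Chick growth is the average daily mass gain between the two captures
(first capture at age 3 +/- 2 days, second at 15 +/- 1 days); survival is
survival from hatching to day 15 posthatch.  Year effects on the
continuous outcomes are tested with mixed models (year as main effect,
breeding pair as random effect) through the inference module; survival
uses a binomial model with a logistic link; intra-seasonal covariate links
(southern-larvae exposure, parental CORT) are per-year regressions
reported as R^2 and P.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .inference import FitError, FitResult, ModelSpec, fit_lmm, lrt

__all__ = [
    "growth_rate",
    "add_growth",
    "survival_summary",
    "year_effect_models",
    "covariate_regressions",
    "survival_model",
    "outcome_models",
]

logger = logging.getLogger(__name__)


def growth_rate(mass_first: float, mass_second: float, interval_days: float) -> float:
    """Average daily mass gain (g/day) between the two captures; undefined
    (NaN) when the second capture is missing (the chick died)."""
    if np.isnan(mass_second) or np.isnan(mass_first):
        return float("nan")
    if interval_days <= 0:
        raise ValueError("capture interval must be positive")
    return (mass_second - mass_first) / interval_days


def add_growth(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized growth column over a chick table (NaN where the chick
    has no second capture)."""
    out = records.copy()
    interval = out["age_second"] - out["age_first"]
    if np.any(interval.dropna() <= 0):
        raise ValueError("capture interval must be positive")
    out["growth"] = (out["mass_second"] - out["mass_first"]) / interval
    return out


def survival_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-year survivor proportions plus the pooled percentage.

    Returns one row per year (proportion, n) and a ``pooled`` row whose
    proportion is the across-year weighted average (total survivors over
    total chicks) expressed the same way.
    """
    if records.empty:
        raise ValueError("no chick records")
    per_year = (
        records.groupby("year")["survived_to_15"]
        .agg(survivors="sum", n="count")
        .reset_index()
    )
    per_year["proportion"] = per_year["survivors"] / per_year["n"]
    pooled = pd.DataFrame([{
        "year": "pooled",
        "survivors": per_year["survivors"].sum(),
        "n": per_year["n"].sum(),
        "proportion": per_year["survivors"].sum() / per_year["n"].sum(),
    }])
    out = pd.concat([per_year, pooled], ignore_index=True)
    out["percent"] = 100.0 * out["proportion"]
    return out


def year_effect_models(records: pd.DataFrame,
                       outcomes=("growth", "mass_second", "tarsus", "hatch_day_june"),
                       group: str = "pair_id") -> pd.DataFrame:
    """Mixed-model year effects for each continuous outcome.

    Fits outcome ~ year (factor) + (1|pair) against the intercept-only
    model and reports the likelihood-ratio chi-square and P.  Requires at
    least two years of data; a single-year table is a caller error.
    """
    if records["year"].nunique() < 2:
        raise ValueError("year-effect models need data from >= 2 years")
    rows = []
    for outcome in outcomes:
        if outcome not in records.columns:
            continue
        data = records.dropna(subset=[outcome])
        full = fit_lmm(data, ModelSpec(f"{outcome} ~ C(year) + (1|{group})"))
        null = fit_lmm(data, ModelSpec(f"{outcome} ~ 1 + (1|{group})"))
        chi2, df, p = lrt(full, null)
        rows.append({"outcome": outcome, "chi2": chi2, "df": df, "p": p, "n": full.n_obs})
    return pd.DataFrame(rows)


def covariate_regressions(records: pd.DataFrame,
                          responses=("growth", "mass_second"),
                          covariates=("larvae_S", "parent_cort")) -> pd.DataFrame:
    """Per-year ordinary regressions of chick outcomes on the
    southern-larvae exposure and parental CORT, reported as R^2 and P."""
    rows = []
    for year in sorted(records["year"].unique()):
        sub = records[records["year"] == year]
        for resp in responses:
            for cov in covariates:
                if resp not in sub.columns or cov not in sub.columns:
                    continue
                data = sub.dropna(subset=[resp, cov])
                if len(data) < 5 or data[cov].nunique() < 2:
                    continue
                fit = smf.ols(f"{resp} ~ {cov}", data=data).fit()
                rows.append({
                    "year": year, "response": resp, "covariate": cov,
                    "slope": float(fit.params[cov]),
                    "r2": float(fit.rsquared),
                    "p": float(fit.pvalues[cov]),
                    "n": int(fit.nobs),
                })
    return pd.DataFrame(rows)


def survival_model(records: pd.DataFrame, covariates=()) -> pd.DataFrame:
    """Binomial (logistic) model of survival to day 15 on year and
    optional covariates, reporting coefficients and z statistics."""
    terms = ["C(year)"] + [c for c in covariates if c in records.columns]
    data = records.dropna(subset=[c for c in covariates if c in records.columns])
    fit = smf.glm(
        f"survived_to_15 ~ {' + '.join(terms)}",
        data=data.assign(survived_to_15=data["survived_to_15"].astype(int)),
        family=sm.families.Binomial(),
    ).fit()
    return pd.DataFrame({
        "coef": fit.params, "se": fit.bse, "z": fit.tvalues, "p": fit.pvalues,
    })


def outcome_models(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The full chick-outcome report: year-effect mixed models, per-year
    covariate regressions, and the binomial survival model."""
    records = add_growth(records) if "growth" not in records.columns else records
    covs = tuple(c for c in ("larvae_S", "parent_cort") if c in records.columns)
    return {
        "year_effects": year_effect_models(records),
        "covariate_regressions": covariate_regressions(records),
        "survival": survival_model(records, covariates=covs),
        "survival_summary": survival_summary(records),
    }
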