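"""Mixed-effects inference for the CORT analysis.

Linear mixed models with a random intercept per breeding pair are fitted
by maximum likelihood (REML optionally, for reporting final-model variance
components), compared with an AIC rule requiring the best model to beat
every nested simpler candidate by at least 2 units, and covariate
probabilities come from likelihood-ratio tests between a model with and an
otherwise identical model without the focal covariate.

Conventions (documented because the AIC rule depends on them): the AIC
parameter count includes the two variance parameters (pair and residual),
AIC = -2 loglik + 2 k; the variance share of the pair intercept is the
intraclass correlation sigma2_pair / (sigma2_pair + sigma2_resid).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "FitResult",
    "FitError",
    "fit_lmm",
    "lrt",
    "aic_select",
    "subgroup_models",
    "significance_stars",
    "formula_terms",
]

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """A mixed-model fit could not be completed (rank deficiency,
    degenerate grouping, or optimizer failure); carries diagnostics."""


def _normalize_term(term: str) -> str:
    parts = sorted(p.strip() for p in term.split(":"))
    return ":".join(parts)


def formula_terms(rhs: str) -> frozenset[str]:
    """Expand a fixed-effects RHS into its normalized term set.

    ``a * b`` expands to {a, b, a:b}; interaction component order is
    canonicalized so ``a:b`` and ``b:a`` are the same term.
    """
    terms: set[str] = set()
    for raw in rhs.split("+"):
        raw = raw.strip()
        if not raw or raw == "1":
            continue
        if "*" in raw:
            factors = [f.strip() for f in raw.split("*")]
            for f in factors:
                terms.add(f)
            terms.add(_normalize_term(":".join(factors)))
        else:
            terms.add(_normalize_term(raw))
    return frozenset(terms)


_RANDOM_RE = re.compile(r"\(\s*1\s*\|\s*([A-Za-z_][A-Za-z0-9_]*)\s*\)")


@dataclass(frozen=True)
class ModelSpec:
    """A model formula in lme4-style notation with a single random
    intercept, e.g. ``log10_cort ~ time + year_num * larvae_S + (1|pair_id)``."""

    formula: str
    reml: bool = False

    def __post_init__(self) -> None:
        if "~" not in self.formula:
            raise ValueError("formula needs a response (lhs ~ rhs)")
        if _RANDOM_RE.search(self.formula) is None:
            raise ValueError("formula needs a random intercept term (1|group)")

    @property
    def response(self) -> str:
        return self.formula.split("~")[0].strip()

    @property
    def group(self) -> str:
        return _RANDOM_RE.search(self.formula).group(1)

    @property
    def fixed_rhs(self) -> str:
        rhs = self.formula.split("~", 1)[1]
        rhs = _RANDOM_RE.sub("", rhs)
        rhs = re.sub(r"\+\s*\+", "+", rhs).strip().strip("+").strip()
        return rhs if rhs else "1"

    @property
    def terms(self) -> frozenset[str]:
        return formula_terms(self.fixed_rhs)

    @property
    def variables(self) -> set[str]:
        toks = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", self.fixed_rhs))
        toks.discard("C")
        return toks | {self.response, self.group}

    def drop_term(self, term: str) -> "ModelSpec":
        terms = set(self.terms) - {_normalize_term(term)}
        return self.with_terms(terms)

    def with_terms(self, terms) -> "ModelSpec":
        rhs = " + ".join(sorted(terms, key=lambda t: (t.count(":"), t))) or "1"
        return ModelSpec(f"{self.response} ~ {rhs} + (1|{self.group})", reml=self.reml)


@dataclass
class FitResult:
    """Estimates and fit statistics for one mixed model."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    var_pair: float
    var_resid: float
    llf: float
    aic: float
    k_params: int
    n_obs: int
    n_groups: int
    converged: bool
    method: str  # "ML" or "REML"
    row_index: tuple = field(default_factory=tuple, repr=False)

    @property
    def icc(self) -> float:
        """Variance share of the pair random intercept."""
        tot = self.var_pair + self.var_resid
        return self.var_pair / tot if tot > 0 else np.nan

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params,
            "se": self.bse,
            "t": self.tvalues,
        })


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit a linear mixed model with a random pair intercept.

    Rows with missing values in any used column are excluded.  Estimation
    is deterministic (statsmodels' default start values, L-BFGS with a CG
    fallback); non-convergence is reported through the ``converged`` flag
    plus a warning, and outright failures raise FitError with diagnostics.
    """
    cols = [c for c in spec.variables if c in table.columns]
    missing = spec.variables - set(cols)
    if missing:
        raise FitError(f"table lacks columns {sorted(missing)}")
    data = table[cols].dropna()
    for flag in ("usable", "has_exposure"):
        if flag in table.columns:
            data = data.loc[table.loc[data.index, flag].astype(bool)]
    n_groups = data[spec.group].nunique()
    if n_groups < 2:
        raise FitError(f"need >= 2 groups, got {n_groups}")

    model = smf.mixedlm(
        f"{spec.response} ~ {spec.fixed_rhs}", data=data, groups=data[spec.group]
    )
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise FitError("fixed-effects design matrix is rank deficient")

    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "cg", "powell"):
            try:
                result = model.fit(reml=spec.reml, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
                logger.debug("fit_lmm: %s failed with %s", method, err)
                continue
            if result.converged and np.isfinite(result.llf):
                break
    if result is None or not np.isfinite(result.llf):
        raise FitError(
            f"mixed model did not converge for {spec.formula!r} "
            f"(n={len(data)}, groups={n_groups})"
        )
    if not result.converged:
        warnings.warn(
            f"mixed model optimizer did not report convergence for {spec.formula!r}",
            RuntimeWarning,
            stacklevel=2,
        )

    k_fe = len(result.fe_params)
    k = k_fe + 2  # pair variance + residual variance
    llf = float(result.llf)
    fe = result.fe_params
    return FitResult(
        spec=spec,
        params=fe,
        bse=result.bse_fe,
        tvalues=fe / result.bse_fe,
        var_pair=float(np.asarray(result.cov_re)[0, 0]),
        var_resid=float(result.scale),
        llf=llf,
        aic=-2.0 * llf + 2.0 * k,
        k_params=k,
        n_obs=int(len(data)),
        n_groups=int(n_groups),
        converged=bool(result.converged),
        method="REML" if spec.reml else "ML",
        row_index=tuple(data.index),
    )


def is_nested(reduced: FitResult | ModelSpec, full: FitResult | ModelSpec) -> bool:
    """True when the reduced model's fixed terms are a strict subset of the
    full model's (same response and grouping assumed)."""
    rt = reduced.spec.terms if isinstance(reduced, FitResult) else reduced.terms
    ft = full.spec.terms if isinstance(full, FitResult) else full.terms
    return rt < ft


def lrt(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in a full model.

    Returns (chi2, df, p) with chi2 = 2 (ll_full - ll_reduced), df the
    difference in parameter counts and p from the chi-square upper tail.
    Identical models give chi2 = 0, p = 1.
    """
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("LRT requires ML fits")
    if full.row_index != reduced.row_index:
        raise ValueError("LRT requires fits on identical rows")
    same = full.spec.terms == reduced.spec.terms
    if not same and not is_nested(reduced, full):
        raise ValueError("models are not nested")
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = full.k_params - reduced.k_params
    if df == 0:
        p = 1.0 if chi2 <= 1e-8 else float("nan")
    else:
        p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def aic_select(candidates: list[FitResult]) -> FitResult:
    """Select the best model by the AIC rule with nested-model guard.

    The model with the lowest AIC is best only if its AIC is at least 2
    units smaller than every nested simpler candidate's; otherwise the
    selection falls back to the simplest model within 2 AIC units of the
    minimum (ties broken by lower AIC) -- the documented tie-break.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    rows = {c.row_index for c in candidates}
    if len(rows) > 1:
        raise ValueError("candidates fitted on differing row sets")

    def rule_ok(m: FitResult) -> bool:
        return all(
            m.aic <= r.aic - 2.0 for r in candidates if is_nested(r, m)
        )

    best = min(candidates, key=lambda c: c.aic)
    if rule_ok(best):
        return best
    within = [c for c in candidates if c.aic <= best.aic + 2.0]
    return min(within, key=lambda c: (len(c.spec.terms), c.aic))


def significance_stars(p: float) -> str:
    """Marker scheme: + for P<0.1, then *, **, *** at 0.05, 0.01, 0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "+"
    return ""


def _backward_select(
    data: pd.DataFrame,
    response: str,
    group: str,
    terms: list[str],
    alpha: float,
) -> tuple[list[str], FitResult | None, dict[str, float]]:
    """Backward elimination by LRT: drop the least significant term while
    its p-value is >= alpha; returns retained terms, the final fit, and
    per-term p-values from dropping each retained term."""
    current = list(terms)
    spec = ModelSpec(f"{response} ~ {' + '.join(current) or '1'} + (1|{group})")
    fit = fit_lmm(data, spec)
    while current:
        pvals = {}
        for t in current:
            reduced = fit_lmm(data, fit.spec.drop_term(t))
            _, _, p = lrt(fit, reduced)
            pvals[t] = p
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha:
            return current, fit, pvals
        current.remove(worst)
        fit = fit_lmm(data, fit.spec.with_terms(current))
    return [], fit, {}


def subgroup_models(
    table: pd.DataFrame,
    candidate_terms: tuple[str, ...] = ("larvae_S", "larvae_N", "time", "sex"),
    response: str = "log10_cort",
    group: str = "pair_id",
    alpha: float = 0.1,
    min_rows: int = 10,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-year models for sample subdivisions (overall, by sex, by phase).

    Separate models are fitted for each subdivision; only terms at least
    marginally significant (P < alpha, default 0.1) are retained via
    backward likelihood-ratio elimination.  Output rows carry estimate,
    SE, P, significance markers and the subset N; a subset with no
    retained term is reported as "-" with its N, and subsets too small to
    fit (fewer than ``min_rows`` rows or ``min_pairs`` pairs) are reported
    as unfit rather than dropped silently.
    """
    out = []
    years = sorted(pd.unique(table["year"]))
    subsets: list[tuple[str, pd.DataFrame]] = []
    for year in years:
        sub = table[table["year"] == year]
        subsets.append((f"overall|{year}", sub))
        if "sex" in table.columns:
            subsets.append((f"females|{year}", sub[sub["sex"] == "F"]))
            subsets.append((f"males|{year}", sub[sub["sex"] == "M"]))
        if "phase" in table.columns:
            subsets.append((f"early|{year}", sub[sub["phase"] == "early"]))
            subsets.append((f"late|{year}", sub[sub["phase"] == "late"]))

    for label, sub in subsets:
        grp, year = label.split("|")
        rec = {"group": grp, "year": year}
        usable = sub
        for flag in ("usable", "has_exposure"):
            if flag in usable.columns:
                usable = usable[usable[flag].astype(bool)]
        n = len(usable)
        if n < min_rows or usable[group].nunique() < min_pairs:
            out.append({**rec, "parameter": "unfit", "n": n,
                        "estimate": np.nan, "se": np.nan, "p": np.nan, "stars": ""})
            continue
        terms = [
            t for t in candidate_terms
            if t in usable.columns and usable[t].nunique() > 1
        ]
        try:
            retained, fit, pvals = _backward_select(usable, response, group, terms, alpha)
        except FitError as err:
            logger.warning("subgroup %s: %s", label, err)
            out.append({**rec, "parameter": "unfit", "n": n,
                        "estimate": np.nan, "se": np.nan, "p": np.nan, "stars": ""})
            continue
        if not retained:
            out.append({**rec, "parameter": "-", "n": n,
                        "estimate": np.nan, "se": np.nan, "p": np.nan, "stars": ""})
            continue
        for t in retained:
            name = _param_name(fit.params.index, t)
            out.append({
                **rec,
                "parameter": t,
                "estimate": float(fit.params[name]),
                "se": float(fit.bse[name]),
                "p": pvals[t],
                "stars": significance_stars(pvals[t]),
                "n": fit.n_obs,
            })
    return pd.DataFrame(out)


def _param_name(index, term: str) -> str:
    """Match a model term to its fitted-coefficient name, ignoring
    interaction component order and treatment-coding suffixes."""
    want = _normalize_term(term)
    hits = []
    for c in index:
        base = c.split("[")[0]
        if _normalize_term(base) == want:
            hits.append(c)
    if len(hits) == 1:
        return hits[0]
    raise KeyError(f"cannot resolve term {term!r} among {list(index)}")
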