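"""Mixed-model inference: estimation oracles, LRT, AIC selection rule."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from larvamatch.inference import (
    FitError,
    FitResult,
    ModelSpec,
    aic_select,
    fit_lmm,
    formula_terms,
    lrt,
    significance_stars,
    subgroup_models,
)


def grouped_data(n_groups=30, per_group=5, sd_group=1.0, sd_resid=0.5, beta=0.8,
                 seed=0, sd_x=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        a = rng.normal(0, sd_group)
        for _ in range(per_group):
            x = rng.normal(0, sd_x)
            y = 1.0 + beta * x + a + rng.normal(0, sd_resid)
            rows.append({"pair_id": f"g{g}", "x": x, "y": y})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_noiseless_identifiability_recovers_slope_exactly(self):
        data = grouped_data(sd_group=0.0, sd_resid=1e-10, beta=2.5, n_groups=10)
        fit = fit_lmm(data, ModelSpec("y ~ x + (1|pair_id)"))
        assert fit.params["x"] == pytest.approx(2.5, abs=1e-6)
        assert fit.params["Intercept"] == pytest.approx(1.0, abs=1e-6)

    def test_variance_components_match_anova_oracle(self):
        # balanced one-way layout: REML variance components equal the
        # classical ANOVA method-of-moments estimators
        g, n = 40, 6
        rng = np.random.default_rng(3)
        groups = np.repeat(np.arange(g), n)
        y = rng.normal(0, 1.0, g)[groups] + rng.normal(0, 0.7, g * n)
        data = pd.DataFrame({"pair_id": groups.astype(str), "y": y})
        means = data.groupby("pair_id")["y"].transform("mean")
        grand = y.mean()
        ssw = float(((y - means) ** 2).sum())
        ssb = float(n * ((data.groupby("pair_id")["y"].mean() - grand) ** 2).sum())
        msw = ssw / (g * n - g)
        msb = ssb / (g - 1)
        var_between = (msb - msw) / n
        fit = fit_lmm(data, ModelSpec("y ~ 1 + (1|pair_id)", reml=True))
        assert fit.var_resid == pytest.approx(msw, rel=1e-3)
        assert fit.var_pair == pytest.approx(var_between, rel=1e-2)
        icc_oracle = var_between / (var_between + msw)
        assert fit.icc == pytest.approx(icc_oracle, abs=0.01)

    def test_matches_lme4_on_small_dataset(self, tmp_path):
        """Independent cross-check of the ML fit against R's lme4."""
        data = grouped_data(n_groups=20, per_group=4, seed=7)
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(y ~ x + (1|pair_id), data=d, REML=FALSE)
            cat(sprintf("%.10f %.10f %.10f\\n", logLik(m), fixef(m)[1], fixef(m)[2]))
        """)
        res = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True,
                             timeout=120)
        assert res.returncode == 0, res.stderr
        llf_r, b0_r, b1_r = map(float, res.stdout.split()[-3:])
        fit = fit_lmm(data, ModelSpec("y ~ x + (1|pair_id)"))
        assert fit.llf == pytest.approx(llf_r, abs=1e-4)
        assert fit.params["Intercept"] == pytest.approx(b0_r, abs=1e-5)
        assert fit.params["x"] == pytest.approx(b1_r, abs=1e-5)

    def test_fewer_than_two_groups_rejected(self):
        data = grouped_data(n_groups=1)
        with pytest.raises(FitError, match="groups"):
            fit_lmm(data, ModelSpec("y ~ x + (1|pair_id)"))

    def test_rank_deficiency_rejected(self):
        data = grouped_data(n_groups=8)
        data["x2"] = 2.0 * data["x"]
        with pytest.raises(FitError, match="rank"):
            fit_lmm(data, ModelSpec("y ~ x + x2 + (1|pair_id)"))

    def test_deterministic_given_data(self):
        data = grouped_data(seed=11)
        a = fit_lmm(data, ModelSpec("y ~ x + (1|pair_id)"))
        b = fit_lmm(data, ModelSpec("y ~ x + (1|pair_id)"))
        assert a.llf == b.llf
        pd.testing.assert_series_equal(a.params, b.params)


class TestLrt:
    def test_identical_models_null_comparison(self):
        data = grouped_data(seed=2)
        spec = ModelSpec("y ~ x + (1|pair_id)")
        a, b = fit_lmm(data, spec), fit_lmm(data, spec)
        chi2, df, p = lrt(a, b)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_chi_square_tail_evaluation(self):
        data = grouped_data(seed=2)
        full = fit_lmm(data, ModelSpec("y ~ x + (1|pair_id)"))
        reduced = fit_lmm(data, ModelSpec("y ~ 1 + (1|pair_id)"))
        # synthetic log-likelihood gap of exactly 2 with one extra parameter
        reduced_mod = FitResult(**{**reduced.__dict__, "llf": full.llf - 2.0})
        chi2, df, p = lrt(full, reduced_mod)
        assert chi2 == pytest.approx(4.0)
        assert df == 1
        assert p == pytest.approx(0.0455, abs=5e-4)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_strong_effect_detected_below_0_001_in_most_replicates(self):
        from larvamatch.synth import GenParams, simulate_cort, simulate_design

        spec = ModelSpec("log10_cort ~ time + year_num + larvae_S + year_num:larvae_S + (1|pair_id)")
        hits = 0
        reps = 25
        for rep in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence([321, rep]))
            params = GenParams()
            data = simulate_cort(simulate_design(params, rng=rng), params, rng=rng)
            full = fit_lmm(data, spec)
            reduced = fit_lmm(data, spec.drop_term("larvae_S"))
            _, _, p = lrt(full, reduced)
            hits += p < 0.001
        assert hits >= 0.95 * reps

    def test_non_nested_rejected(self):
        data = grouped_data(seed=2)
        data["z"] = np.random.default_rng(0).normal(size=len(data))
        a = fit_lmm(data, ModelSpec("y ~ x + (1|pair_id)"))
        b = fit_lmm(data, ModelSpec("y ~ z + (1|pair_id)"))
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)

    def test_differing_rows_rejected(self):
        full = fit_lmm(grouped_data(seed=2), ModelSpec("y ~ x + (1|pair_id)"))
        reduced = fit_lmm(grouped_data(seed=2).iloc[:-4], ModelSpec("y ~ 1 + (1|pair_id)"))
        with pytest.raises(ValueError, match="identical rows"):
            lrt(full, reduced)


def _fake_fit(terms, aic):
    rhs = " + ".join(sorted(terms)) or "1"
    spec = ModelSpec(f"y ~ {rhs} + (1|g)")
    return FitResult(
        spec=spec, params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
        tvalues=pd.Series(dtype=float), var_pair=0.1, var_resid=1.0,
        llf=-aic / 2, aic=aic, k_params=len(spec.terms) + 3, n_obs=100, n_groups=10,
        converged=True, method="ML", row_index=(0,),
    )


class TestAicSelect:
    def test_rule_satisfied_complex_wins(self):
        simple = _fake_fit([], 100.0)
        complex_ = _fake_fit(["a"], 97.0)
        assert aic_select([simple, complex_]) is complex_

    def test_rule_violated_simpler_wins(self):
        simple = _fake_fit([], 100.0)
        complex_ = _fake_fit(["a"], 99.0)
        assert aic_select([simple, complex_]) is simple

    def test_three_model_chain_exhaustive(self):
        # AICs 100 / 99.5 / 97.4: the most complex passes iff
        # 97.4 <= min(100, 99.5) - 2 = 97.5, which holds
        m0 = _fake_fit([], 100.0)
        m1 = _fake_fit(["a"], 99.5)
        m2 = _fake_fit(["a", "b"], 97.4)
        assert aic_select([m0, m1, m2]) is m2
        # nudge the complex model above the threshold: falls back to the
        # simplest model within 2 units of the minimum
        m2b = _fake_fit(["a", "b"], 97.6)
        assert aic_select([m0, m1, m2b]) is m1

    def test_rule_verified_exhaustively_on_constructed_lattice(self):
        terms_sets = [[], ["a"], ["b"], ["a", "b"]]
        rng = np.random.default_rng(17)
        for _ in range(200):
            aics = 100 + rng.uniform(-4, 4, size=4)
            fits = [_fake_fit(t, a) for t, a in zip(terms_sets, aics)]
            chosen = aic_select(fits)
            by_aic = sorted(fits, key=lambda f: f.aic)
            best = by_aic[0]

            def ok(m):
                return all(m.aic <= r.aic - 2 for r in fits
                           if r.spec.terms < m.spec.terms)

            if ok(best):
                assert chosen is best
            else:
                within = [f for f in fits if f.aic <= best.aic + 2]
                expect = min(within, key=lambda f: (len(f.spec.terms), f.aic))
                assert chosen is expect

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            aic_select([])


class TestSubgroupModels:
    @staticmethod
    def _table(beta_s=0.0, seed=0, n_pairs=20, reps=6):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_pairs):
            a = rng.normal(0, 0.1)
            for sex in ("F", "M"):
                for phase in ("early", "late"):
                    for r in range(reps // 2):
                        s = rng.normal(0, 1.0)
                        y = 0.8 + beta_s * s + a + rng.normal(0, 0.2)
                        rows.append({
                            "pair_id": f"p{p}", "sex": sex, "phase": phase,
                            "year": 1, "time": int(phase == "late"),
                            "larvae_S": s, "larvae_N": rng.normal(0, 1.0),
                            "log10_cort": y,
                        })
        return pd.DataFrame(rows)

    def test_no_significant_term_reported_as_dash_with_n(self):
        report = subgroup_models(self._table(beta_s=0.0, seed=5),
                                 candidate_terms=("larvae_S",))
        overall = report[(report.group == "overall")].iloc[0]
        assert overall["parameter"] == "-"
        assert overall["n"] > 0

    def test_strong_negative_effect_retained_with_sign(self):
        report = subgroup_models(self._table(beta_s=-0.5, seed=6))
        overall = report[(report.group == "overall") & (report.parameter == "larvae_S")]
        assert len(overall) == 1
        assert overall["estimate"].iloc[0] < 0
        assert overall["stars"].iloc[0] != ""

    def test_overall_subset_matches_direct_fit(self):
        table = self._table(beta_s=-0.5, seed=6)
        report = subgroup_models(table, candidate_terms=("larvae_S",))
        est = report[(report.group == "overall") & (report.parameter == "larvae_S")]["estimate"].iloc[0]
        direct = fit_lmm(table, ModelSpec("log10_cort ~ larvae_S + (1|pair_id)"))
        assert est == pytest.approx(direct.params["larvae_S"])

    def test_degenerate_subset_reported_unfit(self):
        table = self._table(seed=1).iloc[:8]  # fewer than min_rows
        report = subgroup_models(table, candidate_terms=("larvae_S",))
        assert (report["parameter"] == "unfit").any()


def test_aic_identity_when_adding_a_term():
    data = grouped_data(seed=4)
    full = fit_lmm(data, ModelSpec("y ~ x + (1|pair_id)"))
    reduced = fit_lmm(data, ModelSpec("y ~ 1 + (1|pair_id)"))
    d_ll = full.llf - reduced.llf
    d_k = full.k_params - reduced.k_params
    assert full.aic - reduced.aic == pytest.approx(-2 * d_ll + 2 * d_k, abs=1e-9)


def test_formula_terms_expand_interactions():
    assert formula_terms("a + b") == {"a", "b"}
    assert formula_terms("a * b") == {"a", "b", "a:b"}
    assert formula_terms("b:a") == {"a:b"}


def test_significance_star_scheme():
    assert [significance_stars(p) for p in (0.2, 0.09, 0.04, 0.009, 0.0009)] == \
        ["", "+", "*", "**", "***"]
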