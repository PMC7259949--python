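"""Mixed-effects models, likelihood-ratio tests and age moderation."""
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from patcomp.trialwise import (
    ModelSpec,
    build_nuisance_set,
    fit_mixed_model,
    lrt,
    moderation_by_age,
    fixed_effect_lrt,
    zscore_within_participant,
)
from patcomp.datatypes import LRTResult, MixedModelResult


class TestZScore:
    def test_two_values(self):
        out = zscore_within_participant([2.0, 4.0], ["a", "a"])
        np.testing.assert_allclose(out, [-0.7071067, 0.7071067], atol=1e-6)

    def test_idempotent(self, rng):
        x = rng.standard_normal(50)
        ids = ["a"] * 50
        once = zscore_within_participant(x, ids)
        twice = zscore_within_participant(once, ids)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_constant_values_become_missing(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = zscore_within_participant([3.0, 3.0, 3.0], ["a"] * 3)
        assert np.isnan(out).all()

    def test_per_participant_blocks(self, rng):
        x = np.concatenate([rng.normal(10, 2, 30), rng.normal(-5, 7, 30)])
        ids = ["a"] * 30 + ["b"] * 30
        out = zscore_within_participant(x, ids)
        for g in ("a", "b"):
            block = out[np.array(ids) == g]
            assert block.mean() == pytest.approx(0.0, abs=1e-12)
            assert block.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestNuisanceSets:
    @pytest.mark.parametrize(
        "kind, want",
        [
            ("logit_iv", ["category", "age", "encoding_strength",
                          "roi_selected_activity"]),
            ("logit_dv", ["category", "age", "encoding_strength"]),
            ("ers_iv", ["category", "age", "roi_mean_activity"]),
            ("event_ers", ["category", "age", "within_category_ers"]),
            ("hippo_iv", ["category", "age"]),
        ],
    )
    def test_rule_mandated_sets(self, kind, want):
        assert build_nuisance_set(kind) == want

    def test_unknown_kind_is_error(self):
        with pytest.raises(ValueError, match="unknown analysis kind"):
            build_nuisance_set("banana")


def _simulate_mixed(rng, G=25, n=30, slope=0.5, tau0=0.6, tau1=0.4,
                    family="linear", sigma=1.0, nuis=0.3):
    rows = []
    for g in range(G):
        b0 = rng.normal(0, tau0)
        b1 = rng.normal(0, tau1)
        x = rng.standard_normal(n)
        c = rng.integers(0, 2, n).astype(float)
        eta = 0.2 + (slope + b1) * x + nuis * c + b0
        if family == "linear":
            y = eta + rng.normal(0, sigma, n)
        else:
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        rows.append(pd.DataFrame(
            {"participant_id": f"s{g}", "x": x, "c": c, "y": y}))
    return pd.concat(rows, ignore_index=True)


class TestMixedModel:
    @pytest.mark.parametrize("family", ["linear", "logistic"])
    def test_zero_heterogeneity_matches_pooled(self, rng, family):
        """With no between-participant variance the mixed fixed effects
        collapse to the pooled (logistic) regression within 1e-3."""
        data = _simulate_mixed(rng, G=30, n=80, tau0=0.0, tau1=0.0,
                               family=family)
        spec = ModelSpec(outcome="y", predictor_of_interest="x",
                         nuisance_terms=["c"], family=family)
        res = fit_mixed_model(data, spec)
        X = sm.add_constant(data[["x", "c"]].to_numpy())
        y = data["y"].to_numpy()
        pooled = (sm.OLS(y, X).fit() if family == "linear"
                  else sm.Logit(y, X).fit(disp=0))
        for i, term in enumerate(["Intercept", "x", "c"]):
            assert res.estimate(term) == pytest.approx(pooled.params[i], abs=1e-3)

    def test_recovers_generative_slope(self, rng):
        data = _simulate_mixed(rng, G=40, n=40, slope=0.5)
        spec = ModelSpec(outcome="y", predictor_of_interest="x",
                         nuisance_terms=["c"], family="linear")
        res = fit_mixed_model(data, spec)
        assert res.estimate("x") == pytest.approx(0.5, abs=0.15)
        assert res.random_intercept_var > 0.1
        assert res.random_slope_var > 0.02
        # Wald z is estimate / SE by construction
        assert res.wald_z("x") == pytest.approx(
            res.estimate("x") / res.se("x"), abs=1e-10)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available")
    def test_logistic_fit_matches_lme4_glmer(self, tmp_path, rng):
        """Independent oracle: lme4::glmer with the same uncorrelated
        random-effects structure agrees on coefficients, SDs and loglik."""
        data = _simulate_mixed(rng, G=25, n=40, family="logistic")
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(y ~ x + c + (1|participant_id) + "
            "(0+x|participant_id), data=d, family=binomial)\n"
            "co <- fixef(m)\n"
            "vc <- as.data.frame(VarCorr(m))\n"
            "cat(co[1], co[2], co[3], vc$sdcor[1], vc$sdcor[2], "
            "as.numeric(logLik(m)), sep=',')\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        b0, bx, bc, sd1, sd2, llf = map(float, out.stdout.strip().split(","))
        spec = ModelSpec(outcome="y", predictor_of_interest="x",
                         nuisance_terms=["c"], family="logistic")
        res = fit_mixed_model(data, spec)
        assert res.estimate("Intercept") == pytest.approx(b0, abs=2e-3)
        assert res.estimate("x") == pytest.approx(bx, abs=2e-3)
        assert res.estimate("c") == pytest.approx(bc, abs=2e-3)
        assert np.sqrt(res.random_intercept_var) == pytest.approx(sd1, abs=5e-3)
        assert res.loglik == pytest.approx(llf, abs=5e-3)


class TestLRT:
    def test_identical_models_give_zero(self):
        res = MixedModelResult({"Intercept": (0, 1, 0, 1)}, loglik=-10.0,
                               random_intercept_var=1, random_slope_var=0,
                               n_obs=10, converged=True)
        out = lrt(res, res)
        assert out.chi2 == 0.0 and out.p == 1.0

    def test_known_chi2_tail(self):
        full = MixedModelResult({"Intercept": (0, 1, 0, 1), "x": (0, 1, 0, 1)},
                                loglik=-8.0, random_intercept_var=1,
                                random_slope_var=0, n_obs=10, converged=True)
        red = MixedModelResult({"Intercept": (0, 1, 0, 1)}, loglik=-10.0,
                               random_intercept_var=1, random_slope_var=0,
                               n_obs=10, converged=True)
        out = lrt(full, red)
        assert out.chi2 == pytest.approx(4.0)
        assert out.df == 1
        assert out.p == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-12)
        assert out.p == pytest.approx(0.0455, abs=1e-4)

    def test_negative_delta_floored(self):
        full = MixedModelResult({"Intercept": (0, 1, 0, 1), "x": (0, 1, 0, 1)},
                                loglik=-10.5, random_intercept_var=1,
                                random_slope_var=0, n_obs=10, converged=True)
        red = MixedModelResult({"Intercept": (0, 1, 0, 1)}, loglik=-10.0,
                               random_intercept_var=1, random_slope_var=0,
                               n_obs=10, converged=True)
        with pytest.warns(UserWarning, match="floored"):
            out = lrt(full, red)
        assert out.chi2 == 0.0

    def test_non_nested_is_error(self):
        a = MixedModelResult({"Intercept": (0, 1, 0, 1), "x": (0, 1, 0, 1)},
                             loglik=-1, random_intercept_var=1,
                             random_slope_var=0, n_obs=10, converged=True)
        b = MixedModelResult({"Intercept": (0, 1, 0, 1), "z": (0, 1, 0, 1)},
                             loglik=-1, random_intercept_var=1,
                             random_slope_var=0, n_obs=10, converged=True)
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)

    def test_chi2_invariant_to_predictor_rescaling(self, rng):
        data = _simulate_mixed(rng, G=20, n=30)
        spec = ModelSpec(outcome="y", predictor_of_interest="x",
                         nuisance_terms=["c"], family="linear")
        _, _, t1 = fixed_effect_lrt(data, spec)
        data2 = data.copy()
        data2["x"] = data2["x"] * 37.0
        _, _, t2 = fixed_effect_lrt(data2, spec)
        # pure rescaling (a shift would change the uncorrelated
        # random-slope structure itself)
        assert t1.chi2 == pytest.approx(t2.chi2, rel=1e-4, abs=1e-4)

    def test_wald_and_lrt_agree_at_large_n(self, rng):
        data = _simulate_mixed(rng, G=50, n=50, slope=0.1, tau1=0.3)
        spec = ModelSpec(outcome="y", predictor_of_interest="x",
                         nuisance_terms=[], family="linear")
        full, _, t = fixed_effect_lrt(data, spec)
        z2 = full.wald_z("x") ** 2
        assert abs(z2 - t.chi2) / t.chi2 < 0.15


class TestModeration:
    def test_zero_variance_age_is_error(self, rng):
        data = _simulate_mixed(rng, G=6, n=10)
        data["age"] = 0.0
        spec = ModelSpec(outcome="y", predictor_of_interest="x",
                         nuisance_terms=[], family="linear")
        with pytest.raises(ValueError, match="zero variance"):
            moderation_by_age(data, spec)

    def test_detects_age_dependent_slope(self, rng):
        rows = []
        for g in range(40):
            age_z = rng.standard_normal()
            x = rng.standard_normal(30)
            y = (0.5 - 0.4 * age_z) * x + rng.normal(0, 1, 30)
            rows.append(pd.DataFrame(
                {"participant_id": f"s{g}", "x": x, "y": y, "age": age_z}))
        data = pd.concat(rows, ignore_index=True)
        spec = ModelSpec(outcome="y", predictor_of_interest="x",
                         nuisance_terms=[], family="linear")
        out = moderation_by_age(data, spec)
        assert isinstance(out, LRTResult)
        assert out.p < 0.01

    def test_null_interaction_not_rejected_typically(self, rng):
        data = _simulate_mixed(rng, G=25, n=25, tau1=0.2)
        data["age"] = data["participant_id"].map(
            {f"s{g}": float(rng.standard_normal()) for g in range(25)}
        )
        spec = ModelSpec(outcome="y", predictor_of_interest="x",
                         nuisance_terms=[], family="linear")
        out = moderation_by_age(data, spec)
        assert out.p > 0.01  # a single null draw; calibration tested elsewhere


def test_trial_filters_select_expected_rows():
    from patcomp.trialwise import apply_trial_filter

    d = pd.DataFrame({"condition": ["associative_hit", "associative_miss",
                                    "item_hit", "item_miss"]})
    assert len(apply_trial_filter(d, "all_studied")) == 4
    assert list(apply_trial_filter(d, "associative_hits_only")["condition"]) == \
        ["associative_hit"]
    assert "item_miss" not in set(
        apply_trial_filter(d, "excl_item_miss")["condition"])
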