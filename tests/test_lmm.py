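"""Mixed-model estimation, reporting, selection and its calibration."""

import numpy as np
import pandas as pd
import pytest

from _oracles import bruteforce_mixedlm
from tacstrial import cohort, lmm
from tacstrial.lmm import (
    SELECTED_MODEL,
    FitError,
    ModelSpec,
    compare_models,
    default_model_family,
    fit_model,
    standardized_refit,
)


@pytest.fixture(scope="module")
def default_fit(default_aggregates):
    agg, _ = default_aggregates
    return fit_model(agg, SELECTED_MODEL)


class TestModelSpec:
    def test_marginality_closure(self):
        spec = ModelSpec("m", ("group:session",))
        assert set(spec.terms) == {"group", "session", "group:session"}

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown model term"):
            ModelSpec("m", ("banana",))

    def test_nesting_by_term_sets(self):
        small = ModelSpec("s", ("group", "epoch"))
        large = ModelSpec("l", ("group:session", "epoch"))
        assert small.is_nested_in(large)
        assert not large.is_nested_in(small)


class TestFitModel:
    def test_noise_free_limit_recovers_generative_betas(self):
        model = cohort.GenerativeModel(
            sd_intercept=0.0, sd_epoch_slope=0.0, cell_sd=0.0
        )
        agg = cohort.simulate_epoch_table(model, residual_sd=1e-6, rng_seed=1)
        fit = fit_model(
            agg, ModelSpec("truth", ("group:session", "trial_type", "epoch")),
            standardize=False,
        )
        for name, expect in [
            ("intercept", 600.0),
            ("group_active", 18.78),
            ("session2", -43.55),
            ("session3", -57.03),
            ("trial_type_lpt", 7.33),
            ("epoch", -12.70),
            ("group_active:session2", -21.01),
            ("group_active:session3", -20.57),
        ]:
            assert fit[name].beta == pytest.approx(expect, abs=1e-4)

    def test_reporting_invariants(self, default_fit):
        f = default_fit
        assert f.conditional_r2 >= f.marginal_r2
        assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.n_params)
        for c in f.coefficients.values():
            assert c.ci_low <= c.beta <= c.ci_high
            assert 0 <= c.p <= 1
        assert f.coefficients["intercept"].n == 840
        assert f.coefficients["trial_type_lpt"].n == 420

    def test_single_participant_rejected(self, default_aggregates):
        agg, _ = default_aggregates
        one = agg[agg.participant_id == agg.participant_id.iloc[0]]
        with pytest.raises(FitError, match="fewer than 2 participants"):
            fit_model(one, SELECTED_MODEL)

    def test_rank_deficient_design_rejected(self, default_aggregates):
        agg, _ = default_aggregates
        degenerate = agg.assign(age=1.0)  # constant column, collinear with intercept
        with pytest.raises(FitError, match="rank-deficient"):
            fit_model(degenerate, ModelSpec("m", ("trial_type", "age")))

    def test_missing_columns_rejected(self, default_aggregates):
        agg, _ = default_aggregates
        with pytest.raises(ValueError, match="lacks columns"):
            fit_model(agg.drop(columns=["group"]), SELECTED_MODEL)


class TestStandardized:
    def test_trial_type_std_beta_magnitude(self, default_fit):
        sb = default_fit["trial_type_lpt"].std_beta
        assert sb > 0
        assert 0.04 < sb < 0.2  # reported regime: about 0.09

    def test_standardization_idempotent(self, default_aggregates):
        agg, _ = default_aggregates
        spec = SELECTED_MODEL
        once = standardized_refit(agg, spec)
        std = agg.copy()
        for col in ("median_rt_ms", "epoch"):
            std[col] = (std[col] - std[col].mean()) / std[col].std(ddof=1)
        twice = standardized_refit(std, spec)
        for name in once:
            assert once[name][0] == pytest.approx(twice[name][0], abs=1e-5)

    def test_scale_invariance_of_std_beta(self, default_aggregates):
        agg, _ = default_aggregates
        rng = np.random.default_rng(0)
        ages = dict(
            zip(agg.participant_id.unique(), rng.normal(70, 7, agg.participant_id.nunique()))
        )
        agg = agg.assign(age=agg.participant_id.map(ages))
        spec = ModelSpec("with age", ("group:session", "trial_type", "epoch", "age"))
        a = standardized_refit(agg, spec)["age"][0]
        b = standardized_refit(agg.assign(age=agg.age * 1000), spec)["age"][0]
        assert a == pytest.approx(b, rel=1e-6)

    def test_zero_variance_column_rejected(self, default_aggregates):
        agg, _ = default_aggregates
        with pytest.raises(ValueError, match="zero-variance"):
            standardized_refit(agg.assign(epoch=2.0), SELECTED_MODEL)


class TestRSquared:
    def test_near_perfect_fit_limit(self):
        model = cohort.GenerativeModel(sd_intercept=1e-3, sd_epoch_slope=0.0)
        agg = cohort.simulate_epoch_table(model, residual_sd=1e-3, rng_seed=0)
        fit = fit_model(agg, ModelSpec("truth", ("group:session", "trial_type", "epoch")),
                        standardize=False)
        assert fit.marginal_r2 > 0.999
        assert fit.conditional_r2 > 0.999

    def test_pure_noise_response(self):
        rng = np.random.default_rng(1)
        agg = cohort.simulate_epoch_table(rng_seed=2)
        vals = []
        for seed in range(5):
            noisy = agg.assign(
                median_rt_ms=np.random.default_rng(seed).normal(500, 50, len(agg))
            )
            fit = fit_model(noisy, SELECTED_MODEL, standardize=False)
            vals.append(fit.conditional_r2)
        assert np.mean(vals) < 0.05

    def test_default_study_matches_reported_regime(self, default_fit):
        assert 0.85 <= default_fit.conditional_r2 <= 0.95
        assert 0.05 <= default_fit.marginal_r2 <= 0.15


class TestOracleEquivalence:
    def test_ml_matches_bruteforce_marginal_likelihood(self):
        """Small balanced dataset: statsmodels ML estimates equal direct
        numerical maximization of the profiled marginal likelihood."""
        rng = np.random.default_rng(7)
        rows = []
        for pid in range(4):
            b0, b1 = rng.normal(0, 30), rng.normal(0, 5)
            for epoch in (1, 2):
                for tt in (0, 1):
                    for rep in range(3):
                        mu = 500 - 10 * epoch + 8 * tt + b0 + b1 * epoch
                        rows.append(
                            {
                                "participant_id": f"P{pid}",
                                "epoch": epoch,
                                "lpt": tt,
                                "trial_type": "lpt" if tt else "hpt",
                                "median_rt_ms": mu + rng.normal(0, 12),
                            }
                        )
        data = pd.DataFrame(rows)
        fit = fit_model(data, ModelSpec("toy", ("trial_type", "epoch")),
                        standardize=False)
        oracle = bruteforce_mixedlm(data, ["lpt", "epoch"], n_starts=10, seed=0)
        assert fit["intercept"].beta == pytest.approx(
            oracle["beta"]["intercept"], rel=1e-4
        )
        assert fit["trial_type_lpt"].beta == pytest.approx(
            oracle["beta"]["lpt"], rel=1e-4
        )
        assert fit["epoch"].beta == pytest.approx(oracle["beta"]["epoch"], rel=1e-4)
        assert fit.loglik == pytest.approx(oracle["loglik"], abs=1e-3)


class TestCompareModels:
    def test_duplicate_specs_tie_break_stable(self, default_aggregates):
        agg, _ = default_aggregates
        a = ModelSpec("first", ("group", "epoch"))
        b = ModelSpec("second", ("group", "epoch"))
        comp = compare_models(agg, [a, b])
        assert comp.fits[0].aic == pytest.approx(comp.fits[1].aic)
        assert comp.selected.spec.name == "first"

    def test_aic_lrt_consistency_for_nested_pair(self, default_aggregates):
        """AIC preference flips exactly when the LRT statistic crosses
        2 x (parameter difference)."""
        agg, _ = default_aggregates
        base = SELECTED_MODEL
        bigger = ModelSpec("plus tt:session", base.terms + ("trial_type:session",))
        comp = compare_models(agg, [base, bigger])
        lrt = next(t for t in comp.lr_tests if t.larger == bigger.name)
        aic_small, aic_big = comp.fits[0].aic, comp.fits[1].aic
        assert (aic_big < aic_small) == (lrt.statistic > 2 * lrt.df)
        assert lrt.statistic >= 0

    def test_family_contains_and_selects_sensibly(self, default_aggregates):
        agg, _ = default_aggregates
        comp = compare_models(agg, default_model_family())
        selected_terms = set(comp.selected.spec.terms)
        assert "group:session" in selected_terms
        assert "trial_type:session" not in selected_terms
        assert "group:session:trial_type" not in selected_terms

    def test_needs_two_candidates(self, default_aggregates):
        agg, _ = default_aggregates
        with pytest.raises(ValueError):
            compare_models(agg, [SELECTED_MODEL])
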