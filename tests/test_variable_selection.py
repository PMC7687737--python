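import itertools

import numpy as np
import pandas as pd
import pytest

from readmitsim import (
    GeneratorConfig,
    best_subset_select,
    generate_cohort,
    univariate_screen,
)
from readmitsim.estimators import ModelSpec, fit_logistic
from readmitsim.variable_selection import information_criterion

from conftest import make_clustered_table


@pytest.fixture(scope="module")
def strong_covariate_cohort():
    cfg = GeneratorConfig(
        n_patients=2500,
        frailty_sd=0.0,
        baseline_logit=-1.5,
        covariate_effects=(1.0, 0.0),
        n_constant_covariates=0,
        n_varying_covariates=2,
    )
    return generate_cohort(cfg, seed=31)


class TestScreen:
    def test_alpha_one_keeps_every_converging_candidate(self, strong_covariate_cohort):
        result = univariate_screen(
            strong_covariate_cohort, ["xv1", "xv2"], method="LR", alpha=1.0
        )
        assert result.selected == ["xv1", "xv2"]

    def test_strong_covariate_always_passes(self, strong_covariate_cohort):
        for method in ("LR", "GEE", "CWGEE"):
            result = univariate_screen(
                strong_covariate_cohort, ["xv1"], method=method, alpha=0.1
            )
            assert result.selected == ["xv1"]
            assert result.details.loc[0, "p"] < 1e-10

    def test_noise_covariate_pass_rate_is_calibrated(self):
        """Type-I calibration: a null covariate should pass the P < 0.1
        screen in about 10% of datasets."""
        passes = 0
        trials = 120
        rng = np.random.default_rng(99)
        for t in range(trials):
            n = 600
            table = pd.DataFrame(
                {
                    "patient_id": np.arange(n),
                    "discharge_index": 1,
                    "x1": rng.normal(size=n),
                    "outcome": rng.binomial(1, 0.3, n),
                }
            )
            result = univariate_screen(table, ["x1"], method="LR", alpha=0.1)
            passes += bool(result.selected)
        # 99.9% binomial band around 0.1 for 120 trials
        assert 0.02 <= passes / trials <= 0.19

    def test_failed_candidate_excluded_with_reason(self, strong_covariate_cohort):
        table = strong_covariate_cohort.assign(xbad=1.0)  # constant: collinear with intercept
        result = univariate_screen(table, ["xv1", "xbad"], method="LR", alpha=0.1)
        assert result.selected == ["xv1"]
        row = result.details.set_index("candidate").loc["xbad"]
        assert not row["kept"]
        assert "fail" in row["reason"]

    def test_output_order_follows_input_order(self, strong_covariate_cohort):
        r = univariate_screen(strong_covariate_cohort, ["xv2", "xv1"], "LR", alpha=1.0)
        assert r.selected == ["xv2", "xv1"]

    def test_missing_candidate_rejected(self, strong_covariate_cohort):
        with pytest.raises(KeyError, match="nope"):
            univariate_screen(strong_covariate_cohort, ["nope"], "LR")


def _aic_oracle(table, names):
    """Independent AIC: -2 loglik + 2 (p+1) from a fresh logistic fit."""
    fit = fit_logistic(table, ModelSpec(method="LR", covariate_names=list(names)))
    from readmitsim.estimators import predict_probability

    mu = predict_probability(fit, table)
    y = table["outcome"].to_numpy(float)
    loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    return -2 * loglik + 2 * (len(names) + 1)


class TestBestSubset:
    def test_single_strong_covariate_retained(self, strong_covariate_cohort):
        result = best_subset_select(strong_covariate_cohort, ["xv1"], method="LR")
        assert result.spec.covariate_names == ["xv1"]
        assert result.fit.converged

    def test_matches_exhaustive_enumeration_oracle(self):
        table = make_clustered_table(150, seed=8, max_size=3, beta=(0.7, 0.0, -0.5, 0.0))
        screened = ["x1", "x2", "x3", "x4"]
        result = best_subset_select(table, screened, method="LR", alpha=1.0)
        # alpha=1.0 disables pruning, so the answer is exactly the
        # criterion-optimal subset; recompute it by brute force
        best, best_aic = None, np.inf
        for k in range(len(screened) + 1):
            for names in itertools.combinations(screened, k):
                aic = _aic_oracle(table, names)
                if aic < best_aic:
                    best, best_aic = names, aic
        assert tuple(result.spec.covariate_names) == best
        assert result.criterion == pytest.approx(best_aic, rel=1e-10)

    def test_gee_subset_matches_enumeration_by_same_criterion(self):
        from readmitsim.variable_selection import _fit

        table = make_clustered_table(120, seed=18, max_size=4, beta=(0.8, 0.0, -0.6))
        screened = ["x1", "x2", "x3"]
        result = best_subset_select(table, screened, method="GEE", alpha=1.0)
        best, best_q = None, np.inf
        for k in range(len(screened) + 1):
            for names in itertools.combinations(screened, k):
                q = information_criterion(_fit(table, "GEE", list(names)), table)
                if q < best_q:
                    best, best_q = names, q
        assert tuple(result.spec.covariate_names) == best

    def test_collinear_pair_keeps_exactly_one(self):
        table = make_clustered_table(200, seed=9, beta=(0.9, 0.0))
        table = table.assign(x3=table["x1"])  # exact copy
        result = best_subset_select(table, ["x1", "x3"], method="LR")
        assert len(result.spec.covariate_names) == 1
        assert result.spec.covariate_names[0] in {"x1", "x3"}
        assert any("collinear" in n for n in result.notes)

    def test_retained_covariates_all_significant(self, strong_covariate_cohort):
        result = best_subset_select(
            strong_covariate_cohort, ["xv1", "xv2"], method="LR", alpha=0.05
        )
        from readmitsim import wald_inference

        pvals = wald_inference(result.fit)["p"].iloc[1:]
        assert (pvals < 0.05).all()
        assert set(result.spec.covariate_names) <= {"xv1", "xv2"}

    def test_intercept_only_allowed_and_flagged(self, strong_covariate_cohort):
        result = best_subset_select(
            strong_covariate_cohort, ["xv2"], method="LR", alpha=1e-12
        )
        # xv2 is a null effect; nothing survives pruning at this alpha
        assert result.spec.covariate_names == []
        assert any("intercept-only" in n for n in result.notes)

    def test_selection_invariant_to_row_order(self):
        table = make_clustered_table(150, seed=12, beta=(0.6, -0.4))
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = best_subset_select(table, ["x1", "x2"], method="LR")
        b = best_subset_select(shuffled, ["x1", "x2"], method="LR")
        assert a.spec.covariate_names == b.spec.covariate_names
        np.testing.assert_allclose(a.fit.params, b.fit.params, atol=1e-8)

    def test_empty_screen_list_rejected(self, strong_covariate_cohort):
        with pytest.raises(ValueError, match="empty"):
            best_subset_select(strong_covariate_cohort, [], method="LR")


def test_pipeline_nesting_property(strong_covariate_cohort):
    """final model covariates <= screened <= candidates."""
    candidates = ["xv1", "xv2"]
    screen = univariate_screen(strong_covariate_cohort, candidates, "LR", alpha=0.5)
    assert set(screen.selected) <= set(candidates)
    result = best_subset_select(strong_covariate_cohort, screen.selected, "LR")
    assert set(result.spec.covariate_names) <= set(screen.selected)
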