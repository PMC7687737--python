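import numpy as np
import pandas as pd
import pytest

from readmitsim import (
    GeneratorConfig,
    ModelSpec,
    RankDeficientError,
    fit_cwgee,
    fit_gee,
    fit_logistic,
    generate_cohort,
    predict_probability,
    wald_inference,
)
from readmitsim.estimators import FitResult

from conftest import make_clustered_table, make_singleton_table


@pytest.fixture(scope="module")
def two_by_two_table():
    """x=0: 10 events of 40; x=1: 20 events of 40 — saturated model."""
    x = np.repeat([0.0, 1.0], 40)
    y = np.concatenate([np.ones(10), np.zeros(30), np.ones(20), np.zeros(20)])
    return make_singleton_table(x, y.astype(int))


@pytest.fixture(scope="module")
def clustered_fit_table():
    return make_clustered_table(80, seed=10)


class TestLogistic:
    def test_saturated_two_by_two_closed_form(self, two_by_two_table):
        fit = fit_logistic(two_by_two_table)
        assert fit.intercept == pytest.approx(np.log(10 / 30), abs=1e-8)
        assert fit.coefficients[0] == pytest.approx(np.log((20 / 20) / (10 / 30)), abs=1e-8)
        # fitted probability at x=1 equals the cell frequency 20/40
        assert predict_probability(fit, np.array([[1.0]]))[0] == pytest.approx(0.5, abs=1e-10)

    def test_duplicating_rows_leaves_estimates_unchanged(self, two_by_two_table):
        doubled = pd.concat(
            [
                two_by_two_table,
                two_by_two_table.assign(patient_id=two_by_two_table.patient_id + 1000),
            ],
            ignore_index=True,
        )
        a, b = fit_logistic(two_by_two_table), fit_logistic(doubled)
        np.testing.assert_allclose(a.params, b.params, atol=1e-9)

    def test_matches_statsmodels_glm(self, clustered_fit_table):
        import statsmodels.api as sm

        fit = fit_logistic(clustered_fit_table)
        X = sm.add_constant(clustered_fit_table[["x1", "x2"]])
        ref = sm.GLM(
            clustered_fit_table["outcome"], X, family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(fit.params, ref.params.values, rtol=1e-6)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.naive_covariance)), ref.bse.values, rtol=1e-5
        )

    def test_score_vanishes_at_optimum(self, clustered_fit_table):
        fit = fit_logistic(clustered_fit_table)
        assert fit.converged
        assert fit.score_norm < 1e-6

    def test_separation_is_flagged(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = (x > 0).astype(int)
        fit = fit_logistic(make_singleton_table(x, y))
        assert not fit.converged
        assert fit.message  # names the failure mode rather than silently returning

    def test_rank_deficiency_names_columns(self, clustered_fit_table):
        table = clustered_fit_table.assign(x3=clustered_fit_table["x1"])
        with pytest.raises(RankDeficientError, match="x3|x1"):
            fit_logistic(table, ModelSpec(method="LR", covariate_names=["x1", "x2", "x3"]))

    def test_single_class_rejected(self):
        table = make_singleton_table(np.arange(4.0), np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(table)


class TestGEE:
    def test_singleton_clusters_equal_logistic(self, two_by_two_table):
        lr = fit_logistic(two_by_two_table)
        gee = fit_gee(two_by_two_table)
        np.testing.assert_allclose(gee.params, lr.params, atol=1e-6)

    def test_working_independence_equals_logistic(self, clustered_fit_table):
        lr = fit_logistic(clustered_fit_table)
        gee = fit_gee(
            clustered_fit_table,
            ModelSpec(method="GEE", covariate_names=["x1", "x2"], correlation="independence"),
        )
        np.testing.assert_allclose(gee.params, lr.params, atol=1e-6)

    def test_cluster_order_permutation_invariant(self, clustered_fit_table):
        relabel = {
            pid: new
            for new, pid in enumerate(
                np.random.default_rng(0).permutation(clustered_fit_table["patient_id"].unique())
            )
        }
        permuted = clustered_fit_table.assign(
            patient_id=clustered_fit_table["patient_id"].map(relabel)
        )
        a = fit_gee(clustered_fit_table)
        b = fit_gee(permuted)
        np.testing.assert_allclose(a.params, b.params, atol=1e-9)
        assert a.working_correlation == pytest.approx(b.working_correlation, abs=1e-12)

    def test_estimating_function_vanishes(self, clustered_fit_table):
        for fitter in (fit_gee, fit_cwgee):
            fit = fitter(clustered_fit_table)
            assert fit.converged
            assert fit.score_norm < 1e-6

    def test_sandwich_variance_halves_when_clusters_double(self):
        cfg = dict(max_size=3, beta=(0.5, -0.3), frailty_sd=0.8)
        v_small, v_big = [], []
        for seed in range(6):
            small = make_clustered_table(400, seed=seed, **cfg)
            big = make_clustered_table(800, seed=seed + 100, **cfg)
            v_small.append(np.diag(fit_gee(small).robust_covariance))
            v_big.append(np.diag(fit_gee(big).robust_covariance))
        ratio = np.mean(v_small, axis=0) / np.mean(v_big, axis=0)
        np.testing.assert_allclose(ratio, 2.0, rtol=0.3)

    def test_recovers_effects_without_clustering(self):
        cfg = GeneratorConfig(
            n_patients=2500,
            frailty_sd=0.0,
            baseline_logit=-1.0,
            covariate_effects=(0.5, -0.3),
            n_constant_covariates=1,
            n_varying_covariates=1,
        )
        table = generate_cohort(cfg, seed=17)
        fit = fit_gee(table)
        se = np.sqrt(np.diag(fit.robust_covariance))[1:]
        np.testing.assert_array_less(np.abs(fit.coefficients - [0.5, -0.3]), 3 * se)


class TestCWGEE:
    def test_equal_cluster_sizes_match_unweighted_gee(self):
        table = make_clustered_table(60, seed=20, max_size=3)
        sizes = table.groupby("patient_id").size()
        equal = table[table["patient_id"].isin(sizes[sizes == 3].index)]
        gee, cw = fit_gee(equal), fit_cwgee(equal)
        np.testing.assert_allclose(cw.params, gee.params, atol=1e-6)

    def test_singleton_clusters_equal_logistic(self, two_by_two_table):
        cw = fit_cwgee(two_by_two_table)
        lr = fit_logistic(two_by_two_table)
        np.testing.assert_allclose(cw.params, lr.params, atol=1e-6)

    def test_targets_per_patient_marginal_under_informative_size(self):
        """Under informative cluster size, CWGEE's mean predicted risk on
        first discharges tracks the per-patient (first-discharge) rate,
        while the discharge-weighted logistic fit calibrates to the higher
        all-discharge rate.  Covariates are kept independent of frailty so
        the two marginals differ only through the cluster-size channel."""
        from readmitsim import first_discharges

        for seed in (1, 2, 3):
            cohort = generate_cohort(
                GeneratorConfig(n_patients=2000, frailty_loading=0.0), seed=seed
            )
            first = first_discharges(cohort)
            target = first["outcome"].mean()
            lr_all = fit_logistic(cohort)
            cw = fit_cwgee(cohort)
            gap_lr = abs(predict_probability(lr_all, first).mean() - target)
            gap_cw = abs(predict_probability(cw, first).mean() - target)
            assert gap_cw < gap_lr

    def test_weights_are_inverse_cluster_sizes(self, clustered_fit_table):
        fit = fit_cwgee(clustered_fit_table)
        sizes = clustered_fit_table.groupby("patient_id").size()
        np.testing.assert_allclose(fit.cluster_weights.loc[sizes.index], 1.0 / sizes)


class TestPrediction:
    def test_zero_linear_predictor_gives_half(self):
        fit = _toy_fit(intercept=0.0, coef=[0.0])
        assert predict_probability(fit, np.array([[3.7]]))[0] == 0.5

    def test_extreme_predictor_does_not_overflow(self):
        fit = _toy_fit(intercept=500.0, coef=[500.0])
        with np.errstate(over="raise"):
            p = predict_probability(fit, np.array([[1.0], [-3.0]]))
        assert 0.0 <= p[1] < p[0] <= 1.0


def _toy_fit(intercept, coef, cov=None):
    k = len(coef) + 1
    cov = np.eye(k) if cov is None else np.asarray(cov)
    return FitResult(
        spec=ModelSpec(method="LR", covariate_names=[f"x{i+1}" for i in range(len(coef))]),
        intercept=intercept,
        coefficients=np.asarray(coef, dtype=float),
        naive_covariance=cov,
        robust_covariance=cov,
        working_correlation=0.0,
        cluster_weights=None,
        converged=True,
        n_iterations=1,
        n_obs=10,
        n_clusters=10,
        score_norm=0.0,
    )


class TestWald:
    def test_zero_estimate_gives_p_one(self):
        table = wald_inference(_toy_fit(0.0, [0.0]))
        assert table["p"].tolist() == [1.0, 1.0]

    def test_z_1_96_gives_p_near_05(self):
        fit = _toy_fit(1.959963984540054, [0.0])
        table = wald_inference(fit)
        assert table.loc[0, "p"] == pytest.approx(0.05, abs=1e-9)

    def test_matches_normal_reference_on_fixed_fit(self, clustered_fit_table):
        from scipy import stats

        fit = fit_gee(clustered_fit_table)
        table = wald_inference(fit)
        se = np.sqrt(np.diag(fit.robust_covariance))
        expected = 2 * stats.norm.sf(np.abs(fit.params / se))
        np.testing.assert_allclose(table["p"].to_numpy(), expected, atol=1e-12)

    def test_naive_and_robust_selectable(self, clustered_fit_table):
        fit = fit_gee(clustered_fit_table)
        robust = wald_inference(fit, "robust")["se"].to_numpy()
        naive = wald_inference(fit, "naive")["se"].to_numpy()
        assert not np.allclose(robust, naive)
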