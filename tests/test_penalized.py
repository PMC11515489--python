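"""Penalized solvers and design matrices: optimizer oracles, KKT
conditions, shrinkage behaviour, cross-checks against reference
implementations."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression

from omicspred import (
    ClusterAssignment, ConfigError, GeneratorConfig, ModelSpec, OmicsBlock,
    build_design_matrix, fit_l1_logistic, fit_lasso_cox, generate_cohort,
    lambda_max_cox, lambda_max_logistic, select_lambda,
)
from omicspred.errors import FoldWithoutEventError, SeparationError
from omicspred.penalized import _cox_parts, _logistic_parts, kkt_violation
from tests.conftest import simulate_single_signal


def _survival_data(seed=1, n=20, p=3, log_hrs=(1.0, -0.5, 0.0)):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    t = rng.exponential(1.0 / np.exp(x @ np.asarray(log_hrs)))
    c = rng.exponential(2.0, n)
    return x, np.minimum(t, c), (t <= c).astype(int)


def _binary_data(seed=2, n=30, p=2):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    coef = np.zeros(p)
    coef[0], coef[1] = 1.0, -1.0
    eta = 0.5 + x @ coef
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return x, y


class TestDesignMatrix:
    @pytest.fixture(scope="class")
    def cohort(self):
        return generate_cohort(GeneratorConfig(
            n_patients=80, n_proteins=6, n_mirnas=8,
            n_informative_proteins=2, n_informative_mirnas=2, seed=21))

    def test_demo_block_has_exactly_six_columns(self, cohort):
        spec = ModelSpec.for_outcome(("demo",), "death_transplant")
        x = build_design_matrix(spec, cohort[0])
        assert x.column_names == ["age", "sex_male", "bmi", "ever_smoker",
                                  "nintedanib", "pirfenidone"]

    def test_cluster_label_block_gives_k_minus_1_indicators(self, cohort):
        spec = ModelSpec.for_outcome(("lbl_prot",), "death_transplant")
        labels = ClusterAssignment(cohort[0].patient_ids,
                                   np.arange(cohort[0].n) % 2, k=2)
        x = build_design_matrix(spec, cohort[0], clusters={"prot": labels})
        assert x.column_names == ["lbl_prot_1"]
        assert set(np.unique(x.values)) <= {0.0, 1.0}

    def test_continuous_columns_standardized(self, cohort):
        spec = ModelSpec.for_outcome(("demo", "clin", "raw_prot"),
                                     "death_transplant")
        x = build_design_matrix(spec, cohort[0], omics={"prot": cohort[1]})
        for name in ("age", "bmi", "fvc_pct", "dlco_pct", "prot_1"):
            col = x.values[:, x.column_names.index(name)]
            assert abs(col.mean()) < 1e-10
            assert abs(col.std(ddof=0) - 1.0) < 1e-10

    def test_dlco_imputed_with_training_median_on_test(self, cohort):
        spec = ModelSpec.for_outcome(("clin",), "death_transplant")
        train = cohort[0].subset(np.arange(60))
        test = cohort[0].subset(np.arange(60, 80))
        x_train = build_design_matrix(spec, train)
        x_test = build_design_matrix(spec, test, reference=x_train)
        missing = np.isnan(test.data["dlco_pct"].to_numpy())
        assert missing.any()
        mean, sd = x_train.standardization_stats["dlco_pct"]
        expected = (x_train.dlco_median - mean) / sd
        col = x_test.values[:, x_test.column_names.index("dlco_pct")]
        assert np.allclose(col[missing], expected)

    def test_missing_cluster_labels_rejected(self, cohort):
        spec = ModelSpec.for_outcome(("lbl_mirna",), "death_transplant")
        with pytest.raises(ConfigError, match="lbl_mirna"):
            build_design_matrix(spec, cohort[0])

    def test_unknown_block_rejected(self):
        with pytest.raises(ConfigError, match="unknown blocks"):
            ModelSpec.for_outcome(("demo", "metabolome"), "death_transplant")

    def test_family_outcome_consistency(self):
        with pytest.raises(ConfigError):
            ModelSpec(("demo",), "progression_1yr", "cox")


class TestLassoCox:
    def test_full_shrinkage_at_lambda_max(self):
        x, time, event = _survival_data()
        lam_max = lambda_max_cox(x, time, event)
        fit = fit_lasso_cox(x, time, event, lam_max)
        assert (fit.beta == 0.0).all()
        fit2 = fit_lasso_cox(x, time, event, 2 * lam_max)
        assert (fit2.beta == 0.0).all()

    def test_unpenalized_fit_matches_generic_optimizer(self):
        x, time, event = _survival_data()
        fit = fit_lasso_cox(x, time, event, 0.0)
        res = minimize(lambda b: _cox_parts(x @ b, time, event)[0],
                       np.zeros(x.shape[1]), method="BFGS",
                       options={"gtol": 1e-10})
        assert np.abs(fit.beta - res.x).max() < 1e-4

    def test_matches_reference_coxnet_at_positive_lambda(self):
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        x, time, event = _survival_data(seed=5, n=120, p=6,
                                        log_hrs=(0.8, -0.6, 0.4, 0, 0, 0))
        lam = 0.3 * lambda_max_cox(x, time, event)
        ours = fit_lasso_cox(x, time, event, lam)
        ref = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[lam],
                                     normalize=False, tol=1e-9)
        ref.fit(x, Surv.from_arrays(event.astype(bool), time))
        assert np.abs(ours.beta - ref.coef_[:, 0]).max() < 1e-3

    def test_breslow_tie_handling(self):
        # heavy ties; oracle is the generic optimizer on the same loss
        rng = np.random.default_rng(8)
        x = rng.normal(size=(25, 2))
        time = rng.integers(1, 5, size=25).astype(float)
        event = rng.integers(0, 2, size=25)
        event[0] = 1
        fit = fit_lasso_cox(x, time, event, 0.0)
        res = minimize(lambda b: _cox_parts(x @ b, time, event)[0],
                       np.zeros(2), method="BFGS", options={"gtol": 1e-10})
        assert np.abs(fit.beta - res.x).max() < 1e-4

    def test_all_censored_rejected(self):
        x, time, _ = _survival_data()
        with pytest.raises(ConfigError, match="event"):
            fit_lasso_cox(x, time, np.zeros_like(time, dtype=int), 0.1)

    def test_non_finite_design_rejected(self):
        x, time, event = _survival_data()
        x[0, 0] = np.nan
        with pytest.raises(ConfigError, match="non-finite"):
            fit_lasso_cox(x, time, event, 0.1)

    def test_objective_monotone_and_kkt(self):
        x, time, event = _survival_data(seed=4, n=60, p=5,
                                        log_hrs=(1.0, -0.5, 0, 0, 0))
        lam = 0.4 * lambda_max_cox(x, time, event)
        fit = fit_lasso_cox(x, time, event, lam)
        assert all(np.diff(fit.objective_path) <= 1e-12)
        assert kkt_violation(fit, x, time=time, event=event) <= lam + 1e-5

    def test_coefficient_file_round_trip(self, tmp_path):
        x, time, event = _survival_data(seed=11, n=40, p=3)
        lam = 0.3 * lambda_max_cox(x, time, event)
        fit = fit_lasso_cox(x, time, event, lam)
        path = tmp_path / "fit.tsv"
        fit.to_file(path)
        back = fit.__class__.from_file(path)
        assert back.family == "cox"
        assert back.column_names == fit.column_names
        assert np.allclose(back.beta, fit.beta)
        assert back.lam == fit.lam

    def test_predictions_invariant_to_column_order(self):
        x, time, event = _survival_data(seed=6, n=80, p=5,
                                        log_hrs=(1.0, -0.5, 0.3, 0, 0))
        lam = 0.2 * lambda_max_cox(x, time, event)
        fit = fit_lasso_cox(x, time, event, lam)
        perm = [3, 1, 4, 0, 2]
        fit_p = fit_lasso_cox(x[:, perm], time, event, lam)
        assert np.allclose(x @ fit.beta, x[:, perm] @ fit_p.beta, atol=1e-6)


class TestL1Logistic:
    def test_full_shrinkage_gives_prevalence_intercept(self):
        x, y = _binary_data()
        lam_max = lambda_max_logistic(x, y)
        fit = fit_l1_logistic(x, y, lam_max)
        assert (fit.beta == 0.0).all()
        assert fit.intercept == pytest.approx(np.log(y.mean() / (1 - y.mean())),
                                              abs=1e-8)

    def test_unpenalized_fit_matches_generic_optimizer(self):
        x, y = _binary_data()
        fit = fit_l1_logistic(x, y, 0.0)
        res = minimize(lambda v: _logistic_parts(v[0] + x @ v[1:], y)[0],
                       np.zeros(3), method="BFGS", options={"gtol": 1e-12})
        assert np.abs(np.r_[fit.intercept, fit.beta] - res.x).max() < 1e-4

    def test_matches_reference_saga_solver(self):
        x, y = _binary_data(seed=7, n=150, p=4)
        lam = 0.3 * lambda_max_logistic(x, y)
        ours = fit_l1_logistic(x, y, lam)
        # sklearn minimizes sum log-loss + (1/C)||b||_1; ours is mean
        # deviance (=2*mean log-loss) + lam*||b||_1, hence C = 2/(n*lam)
        ref = LogisticRegression(penalty="l1", solver="saga",
                                 C=2 / (len(y) * lam), tol=1e-12,
                                 max_iter=200000).fit(x, y)
        assert np.abs(ours.beta - ref.coef_[0]).max() < 1e-6
        assert abs(ours.intercept - ref.intercept_[0]) < 1e-6

    def test_perfect_separation_raises_without_penalty(self):
        x = np.linspace(-2, 2, 20).reshape(-1, 1)
        y = (x[:, 0] > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_l1_logistic(x, y, 0.0)
        fit = fit_l1_logistic(x, y, 0.05)   # penalty restores a finite optimum
        assert np.isfinite(fit.beta).all()

    def test_single_class_rejected(self):
        x, y = _binary_data()
        with pytest.raises(ConfigError, match="both classes"):
            fit_l1_logistic(x, np.ones_like(y), 0.1)


class TestSelectLambda:
    def test_planted_signal_selected_by_cv(self, planted_signal_fits):
        hits = sum("x0" in fit.selected for fit in planted_signal_fits)
        assert hits >= 18  # >= 90% of 20 seeds

    def test_pure_noise_keeps_nearly_empty_models(self):
        sparse = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=(200, 20))
            t = rng.exponential(1.0, 200)
            c = rng.exponential(2.0, 200)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            sel = select_lambda(x, family="cox", time=time, event=event,
                                n_folds=10, seed=seed)
            fit = fit_lasso_cox(x, time, event, sel.lam)
            sparse += len(fit.selected) <= 2
        assert sparse >= 16  # >= 80% of 20 seeds

    def test_grid_spans_lambda_max_down_to_ratio(self):
        x, time, event = _survival_data(seed=9, n=60, p=4,
                                        log_hrs=(1.0, 0, 0, 0))
        sel = select_lambda(x, family="cox", time=time, event=event,
                            n_folds=5, seed=0)
        assert sel.grid.size == 100
        assert sel.grid[0] == pytest.approx(lambda_max_cox(x, time, event))
        assert sel.grid[-1] == pytest.approx(sel.grid[0] * 1e-3)
        assert np.isfinite(sel.cv_criterion).all()

    def test_fold_without_events_raises(self):
        x, time, event = _survival_data(seed=10, n=30, p=2, log_hrs=(0.5, 0))
        event[:] = 0
        event[:3] = 1
        with pytest.raises(FoldWithoutEventError):
            select_lambda(x, family="cox", time=time, event=event,
                          n_folds=10, seed=0)

    def test_nonzero_count_zero_at_lambda_max_and_monotone_in_lambda(self):
        # solution-path sanity over 10 random datasets
        from omicspred.penalized import fit_path

        violations = 0
        for seed in range(10):
            x, time, event = _survival_data(
                seed=30 + seed, n=60, p=6, log_hrs=(1.0, -0.7, 0.4, 0, 0, 0))
            lam_max = lambda_max_cox(x, time, event)
            grid = np.geomspace(lam_max, 1e-3 * lam_max, 50)
            fits = fit_path(x, grid, family="cox", time=time, event=event)
            nnz = [len(f.selected) for f in fits]
            assert nnz[0] == 0
            violations += any(np.diff(nnz) < 0)
        # variables may occasionally leave the active set as lambda falls,
        # but the count must be non-increasing in lambda for most paths
        assert violations <= 2
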