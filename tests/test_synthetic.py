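"""Generator contracts: shapes, determinism, outcome definitions, planted
effects recoverable by independent estimators."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from omicspred import (
    ConfigError, GeneratorConfig, derive_binary_outcomes, generate_cohort,
    summarize_cohort,
)
from omicspred.synthetic import TIME_TO_EVENT_OUTCOMES


class TestGenerateCohort:
    def test_shapes_match_study_conditions(self, default_cohort):
        cohort, proteins, mirnas = default_cohort
        assert cohort.n == 231
        assert proteins.values.shape == (231, 44)
        assert mirnas.values.shape == (231, 472)
        assert list(proteins.patient_ids) == list(cohort.patient_ids)

    def test_bit_identical_given_seed(self):
        config = GeneratorConfig(n_patients=60, n_proteins=8, n_mirnas=9,
                                 n_informative_proteins=3,
                                 n_informative_mirnas=3, seed=42)
        a = generate_cohort(config)
        b = generate_cohort(config)
        pd.testing.assert_frame_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].values, b[1].values)
        assert np.array_equal(a[2].values, b[2].values)

    def test_times_positive_events_binary(self, default_cohort):
        cohort = default_cohort[0]
        for outcome in TIME_TO_EVENT_OUTCOMES:
            assert (cohort.times(outcome) > 0).all()
            assert set(np.unique(cohort.events(outcome))) <= {0, 1}
        assert not cohort.data["fvc_pct"].isna().any()

    def test_dlco_missing_count_within_binomial_interval(self):
        config = GeneratorConfig(dlco_missing_frac=0.255, seed=7)
        cohort = generate_cohort(config)[0]
        missing = int(cohort.data["dlco_pct"].isna().sum())
        mean = 0.255 * 231
        half = 1.96 * np.sqrt(231 * 0.255 * 0.745)
        assert mean - half <= missing <= mean + half

    def test_null_effects_give_null_cox_fit(self):
        config = GeneratorConfig(n_patients=2000, n_proteins=4, n_mirnas=4,
                                 n_informative_proteins=2,
                                 n_informative_mirnas=2,
                                 endotype_log_hr=0.0, protein_separation=0.0,
                                 seed=3)
        cohort = generate_cohort(config)[0]
        df = pd.DataFrame({
            "time": cohort.times("death_transplant"),
            "event": cohort.events("death_transplant"),
            "endo": (cohort.data["true_endotype"] == 2).astype(float),
        })
        cph = CoxPHFitter().fit(df, "time", "event")
        assert abs(cph.params_["endo"]) < 0.1

    def test_planted_log_hr_recovered_within_2se(self):
        config = GeneratorConfig(n_patients=2000, n_proteins=4, n_mirnas=4,
                                 n_informative_proteins=2,
                                 n_informative_mirnas=2, seed=9)
        cohort = generate_cohort(config)[0]
        df = pd.DataFrame({
            "time": cohort.times("death_transplant"),
            "event": cohort.events("death_transplant"),
            "endo": (cohort.data["true_endotype"] == 2).astype(float),
        })
        # condition on the other hazard drivers so the endotype coefficient
        # is estimated at (approximately) its generating value
        for col in ("age", "sex_male", "bmi", "ever_smoker", "fvc_pct"):
            df[col] = cohort.data[col]
        df["dlco_pct"] = cohort.data["dlco_pct"].fillna(
            cohort.data["dlco_pct"].median())
        cph = CoxPHFitter().fit(df, "time", "event")
        est, se = cph.params_["endo"], cph.standard_errors_["endo"]
        assert abs(est - config.endotype_log_hr) < 2 * se

    @pytest.mark.parametrize("hazards", [(0.004, 0.008, 0.016)])
    def test_event_rate_monotone_in_baseline_hazard(self, hazards):
        rates = []
        for h in hazards:
            config = GeneratorConfig(n_patients=2000, n_proteins=4,
                                     n_mirnas=4, n_informative_proteins=2,
                                     n_informative_mirnas=2,
                                     baseline_hazard=h, seed=11)
            cohort = generate_cohort(config)[0]
            rates.append(cohort.events("death_transplant").mean())
        assert rates[0] <= rates[1] <= rates[2]

    def test_endotypes_linearly_separable_in_informative_subspace(self):
        config = GeneratorConfig(n_patients=2000, n_proteins=10, n_mirnas=4,
                                 n_informative_proteins=6,
                                 n_informative_mirnas=2,
                                 protein_separation=3.0, seed=13)
        cohort, proteins, _ = generate_cohort(config)
        x = proteins.values[:, :6]
        y = cohort.data["true_endotype"]
        lda = LinearDiscriminantAnalysis().fit(x, y)
        assert lda.score(x, y) > 0.99


class TestBinaryOutcomes:
    @pytest.fixture
    def base(self, small_cohort):
        return small_cohort[0].data.copy()

    def test_decline_exactly_10_is_not_an_event(self, base):
        from omicspred import CohortTable
        base.loc[0, "fvc_change_1yr"] = -10.0
        out = derive_binary_outcomes(CohortTable(base))
        assert out.data.loc[0, "fvc_decline_gt10_1yr"] == 0.0

    def test_decline_above_10_is_an_event(self, base):
        from omicspred import CohortTable
        base.loc[0, "fvc_change_1yr"] = -10.1
        out = derive_binary_outcomes(CohortTable(base))
        assert out.data.loc[0, "fvc_decline_gt10_1yr"] == 1.0

    def test_death_before_12_months_is_progression(self, base):
        from omicspred import CohortTable
        base.loc[0, "death_transplant_time"] = 6.0
        base.loc[0, "death_transplant_event"] = 1
        base.loc[0, "fvc_change_1yr"] = 5.0   # improving lung function
        base.loc[0, "dlco_change_1yr"] = 5.0
        out = derive_binary_outcomes(CohortTable(base))
        assert out.data.loc[0, "progression_1yr"] == 1.0
        assert out.data.loc[0, "fvc_decline_gt10_1yr"] == 0.0

    def test_missing_change_propagates_to_missing_label(self, base):
        from omicspred import CohortTable
        base.loc[0, "fvc_change_1yr"] = np.nan
        base.loc[0, "death_transplant_time"] = 30.0
        base.loc[0, "death_transplant_event"] = 0
        base.loc[0, "dlco_change_1yr"] = 0.0
        out = derive_binary_outcomes(CohortTable(base))
        assert np.isnan(out.data.loc[0, "fvc_decline_gt10_1yr"])
        assert np.isnan(out.data.loc[0, "progression_1yr"])


class TestSummary:
    def test_event_percentages_rounded_to_integer(self, default_cohort):
        from omicspred import CohortTable
        df = default_cohort[0].data.copy()
        df["death_transplant_event"] = np.r_[np.ones(95), np.zeros(136)].astype(int)
        df["death_transplant_dlco15_event"] = np.r_[np.ones(116), np.zeros(115)].astype(int)
        summary = summarize_cohort(CohortTable(df)).set_index("item")
        assert summary.loc["death_transplant", "formatted"] == "95 (41%)"
        assert summary.loc["death_transplant_dlco15", "formatted"] == "116 (50%)"

    def test_zero_events_give_zero_percent(self, small_cohort):
        from omicspred import CohortTable
        df = small_cohort[0].data.copy()
        df["death_transplant_event"] = 0
        summary = summarize_cohort(CohortTable(df)).set_index("item")
        assert summary.loc["death_transplant", "spread"] == 0

    def test_covariates_reported_as_mean_sd(self, default_cohort):
        summary = summarize_cohort(default_cohort[0]).set_index("item")
        age = summary.loc["age"]
        assert age["kind"] == "covariate"
        assert 60 < age["value"] < 80


class TestConfigValidation:
    def test_props_must_match_endotype_count(self):
        with pytest.raises(ConfigError, match="endotype_props"):
            GeneratorConfig(endotype_props=(0.5, 0.3, 0.2))

    def test_props_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            GeneratorConfig(endotype_props=(0.6, 0.5))

    def test_non_finite_values_rejected(self):
        with pytest.raises(ConfigError, match="finite"):
            GeneratorConfig(baseline_hazard=float("nan"))

    def test_informative_count_bounded(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_proteins=4, n_informative_proteins=5)
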