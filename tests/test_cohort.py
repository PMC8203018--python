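"""Comorbidity flags, prevalence tabulation and logistic models."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import fsnlp
from fsnlp import (
    CohortGeneratorSpec,
    DiagnosisEvent,
    derive_condition_flag,
    fit_access_model,
    fit_mention_model,
    generate_cohort,
    mention_and_access_rates,
    tabulate_prevalence,
    unadjusted_or,
)

CODES = {"309.81", "F43.10"}


def ev(setting, date, code="309.81"):
    system = "ICD9" if code[0].isdigit() else "ICD10"
    return DiagnosisEvent("p1", code, system, setting, date)


class TestConditionFlag:
    def test_two_same_day_outpatient_does_not_qualify(self):
        assert not derive_condition_flag([ev("outpatient", "2015-01-01"), ev("outpatient", "2015-01-01")], CODES)

    def test_one_inpatient_qualifies(self):
        assert derive_condition_flag([ev("inpatient", "2015-01-01")], CODES)

    def test_two_separate_day_outpatient_qualifies(self):
        assert derive_condition_flag([ev("outpatient", "2015-01-01"), ev("outpatient", "2015-01-02")], CODES)

    def test_no_qualifying_events(self):
        assert not derive_condition_flag([], CODES)
        assert not derive_condition_flag([ev("outpatient", "2015-01-01", "250.00")], CODES)

    def test_order_and_duplication_invariance(self):
        events = [ev("outpatient", "2015-01-01"), ev("outpatient", "2015-02-01")]
        assert derive_condition_flag(events[::-1], CODES)
        assert derive_condition_flag(events + events, CODES)

    def test_unknown_code_system_rejected(self):
        with pytest.raises(ValueError, match="code_system"):
            DiagnosisEvent("p1", "309.81", "ICD8", "outpatient", "2015-01-01")


@pytest.fixture(scope="module")
def small_cohort():
    spec = dataclasses.replace(CohortGeneratorSpec(), n=4000, seed=5)
    cohort, events = generate_cohort(spec)
    return spec, cohort, events


class TestPrevalence:
    def test_counts_partition_the_cohort(self, small_cohort):
        _, cohort, _ = small_cohort
        table = tabulate_prevalence(cohort, "gender")
        assert int(table["n"].to_numpy().sum()) == len(cohort)

    def test_column_percents_sum_to_100(self, small_cohort):
        _, cohort, _ = small_cohort
        table = tabulate_prevalence(cohort, "age_group")
        sums = table["col_pct"].sum(axis=0)
        assert np.allclose(sums, 100.0, atol=0.05)

    def test_tabulated_shares_near_generating_marginals(self, small_cohort):
        """Binomial check: the male share of each column is within 2 SE-ish
        of the generating 86.93% marginal."""
        spec, cohort, _ = small_cohort
        table = tabulate_prevalence(cohort, "gender")
        n_col = table["n"].sum(axis=0)
        p = spec.gender["male"]
        for outcome in table["n"].columns:
            n = n_col[outcome]
            se = math.sqrt(p * (1 - p) / n)
            # Mention/access shift the male share upward (male OR > 1), so
            # allow the generating effect plus sampling noise.
            assert abs(table["n"].loc["male", outcome] / n - p) < 0.03 + 2 * se

    def test_chi2_p_attached(self, small_cohort):
        _, cohort, _ = small_cohort
        table = tabulate_prevalence(cohort, "ptsd")
        assert 0.0 <= table.attrs["chi2_p"] <= 1.0

    def test_empty_cohort_and_unknown_covariate_error(self, small_cohort):
        _, cohort, _ = small_cohort
        with pytest.raises(ValueError):
            tabulate_prevalence(cohort.iloc[0:0], "gender")
        with pytest.raises(ValueError):
            tabulate_prevalence(cohort, "nonexistent")


class TestRates:
    def test_rates_against_reference_margins(self):
        """Rates computed from the published cross-tab match its printed
        percentages."""
        from fsnlp.reference import DOCUMENTATION_COUNTS

        gender, mention, access = [], [], []
        for level, (no_doc, doc_no, doc_yes) in DOCUMENTATION_COUNTS["gender"].items():
            n = no_doc + doc_no + doc_yes
            gender += [level] * n
            mention += [False] * no_doc + [True] * (doc_no + doc_yes)
            access += [False] * (no_doc + doc_no) + [True] * doc_yes
        rates = mention_and_access_rates(
            pd.DataFrame({"gender": gender, "mention": mention, "access": access})
        )
        assert rates["gender"]["male"]["mention_rate"] == pytest.approx(0.098, abs=0.001)
        assert rates["gender"]["female"]["mention_rate"] == pytest.approx(0.071, abs=0.001)
        assert rates["gender"]["female"]["access_given_mention"] == pytest.approx(0.209, abs=0.002)

    def test_no_mentions_gives_nan_access(self):
        df = pd.DataFrame({"mention": [False] * 5, "access": [False] * 5})
        rates = mention_and_access_rates(df)
        assert rates["overall"]["mention_rate"] == 0.0
        assert math.isnan(rates["overall"]["access_given_mention"])


class TestLogisticModels:
    def test_unadjusted_or_equals_cross_product_ratio(self, small_cohort):
        _, cohort, _ = small_cohort
        a = int((cohort.ptsd & cohort.mention).sum())
        b = int((cohort.ptsd & ~cohort.mention).sum())
        c = int((~cohort.ptsd & cohort.mention).sum())
        d = int((~cohort.ptsd & ~cohort.mention).sum())
        assert unadjusted_or(cohort, "ptsd") == pytest.approx(a * d / (b * c), abs=1e-6)

    def test_mention_model_recovers_male_or(self, cohort50k):
        spec, cohort = cohort50k
        table = fit_mention_model(cohort)
        row = table.set_index("term").loc["gender[male]"]
        true_beta = spec.mention_log_odds["gender[male]"]
        assert abs(row["coef"] - true_beta) <= 3 * row["se"]
        assert row["ci_low"] < math.exp(true_beta) + 0.3
        assert row["ci_low"] < row["or"] < row["ci_high"]

    def test_access_model_runs_on_mention_subset(self, cohort50k):
        spec, cohort = cohort50k
        table = fit_access_model(cohort)
        assert table.attrs["n"] <= int(cohort.mention.sum())  # complete-case drops more
        assert {"or", "ci_low", "ci_high", "p"} <= set(table.columns)

    def test_constant_outcome_errors(self, small_cohort):
        _, cohort, _ = small_cohort
        bad = cohort.copy()
        bad["mention"] = True
        bad["access"] = False
        with pytest.raises(ValueError, match="constant"):
            fit_mention_model(bad)

    def test_complete_case_on_smoking(self, cohort50k):
        _, cohort = cohort50k
        table = fit_mention_model(cohort)
        assert table.attrs["n"] == int((cohort.smoking != "missing").sum())
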