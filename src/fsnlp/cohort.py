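"""Cohort analysis: comorbidity flags, prevalence tables, logistic models.

A patient's documentation status has three levels: no documentation of any
firearm term, documentation without access, and documentation with access.
Comorbidity flags follow the standard administrative-data rule (at least two
outpatient codes on separate days, or one inpatient code).  Two adjusted
logistic models are fitted: any firearm mention over the whole cohort, and
access among those with a mention.  Odds ratios are exponentiated
coefficients with 95% Wald intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)

#: Binary comorbidity/screen flags used as model covariates.
CONDITION_COLUMNS = ["mdd", "ptsd", "bipolar", "oud", "alcohol", "drug", "chronic_pain", "tbi", "mst"]

#: Categorical covariates with their reference levels (first entry).
CATEGORICAL_LEVELS = {
    "gender": ["female", "male"],
    "age_group": ["<30", "30-49", "50+"],
    "race_ethnicity": ["White", "Black", "Hispanic", "Other"],
    "smoking": ["never", "past", "current"],
}

COUNT_COLUMNS = ["ed_visits", "mh_visits"]

OUTCOME_LEVELS = ["no_documentation", "documentation_no_access", "documentation_access"]


@dataclass(frozen=True)
class DiagnosisEvent:
    patient_id: str
    code: str
    code_system: str  # ICD9 | ICD10
    setting: str  # inpatient | outpatient
    date: str  # ISO-8601 calendar date

    def __post_init__(self) -> None:
        if self.code_system not in {"ICD9", "ICD10"}:
            raise ValueError(f"unknown code_system: {self.code_system!r}")
        if self.setting not in {"inpatient", "outpatient"}:
            raise ValueError(f"unknown setting: {self.setting!r}")
        pd.Timestamp(self.date)  # raises on unparseable dates


def derive_condition_flag(events: Iterable[DiagnosisEvent], code_set: set[str]) -> bool:
    """True iff >=1 inpatient code, or >=2 outpatient codes on separate days.

    Events must belong to a single patient.  The rule is invariant to event
    order and to duplicated identical events (same-day outpatient repeats do
    not qualify).
    """
    outpatient_days: set[str] = set()
    for ev in events:
        if ev.code not in code_set:
            continue
        if ev.setting == "inpatient":
            return True
        outpatient_days.add(str(pd.Timestamp(ev.date).date()))
    return len(outpatient_days) >= 2


def derive_condition_flags(
    events: pd.DataFrame,
    code_sets: dict[str, set[str]],
    patient_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-patient boolean flag table, one column per condition code set.

    `events` columns: patient_id, code, code_system, setting, date.
    Patients with no events get all-False rows.
    """
    flags = pd.DataFrame(False, index=pd.Index(patient_ids, name="patient_id"), columns=list(code_sets))
    for pid, grp in events.groupby("patient_id"):
        if pid not in flags.index:
            continue
        evs = [
            DiagnosisEvent(str(pid), r.code, r.code_system, r.setting, str(r.date))
            for r in grp.itertuples(index=False)
        ]
        for cond, codes in code_sets.items():
            flags.loc[pid, cond] = derive_condition_flag(evs, codes)
    return flags


def documentation_status(cohort: pd.DataFrame) -> pd.Series:
    """Three-level outcome from the mention/access booleans."""
    if (cohort["access"] & ~cohort["mention"]).any():
        raise ValueError("access=True requires mention=True")
    return pd.Series(
        np.select(
            [~cohort["mention"], cohort["mention"] & ~cohort["access"]],
            OUTCOME_LEVELS[:2],
            default=OUTCOME_LEVELS[2],
        ),
        index=cohort.index,
        name="documentation",
    )


def tabulate_prevalence(cohort: pd.DataFrame, covariate: str) -> pd.DataFrame:
    """Cross-tab of a covariate against the three documentation levels.

    Counts plus column percents (each outcome column sums to 100%), with a
    chi-squared test of independence attached as DataFrame.attrs
    ['chi2_p'].  Boolean covariates are tabulated as False/True rows.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    if covariate not in cohort.columns:
        raise ValueError(f"unknown covariate: {covariate!r}")
    status = documentation_status(cohort)
    counts = pd.crosstab(cohort[covariate], status)
    counts = counts.reindex(columns=OUTCOME_LEVELS, fill_value=0)
    if covariate in CATEGORICAL_LEVELS:
        order = [l for l in CATEGORICAL_LEVELS[covariate] if l in counts.index]
        extra = [l for l in counts.index if l not in order]
        counts = counts.reindex(order + extra)
    pct = 100.0 * counts / counts.sum(axis=0).replace(0, np.nan)
    table = pd.concat({"n": counts, "col_pct": pct.round(2)}, axis=1)
    nonzero = counts.loc[:, counts.sum(axis=0) > 0]
    nonzero = nonzero.loc[nonzero.sum(axis=1) > 0]
    if nonzero.shape[0] > 1 and nonzero.shape[1] > 1:
        table.attrs["chi2_p"] = float(chi2_contingency(nonzero.to_numpy())[1])
    else:
        table.attrs["chi2_p"] = float("nan")
    return table


def mention_and_access_rates(cohort: pd.DataFrame) -> dict:
    """Overall and subgroup mention and access-given-mention proportions.

    mention rate = mentions / N; access rate = access / mentions (NaN when
    there are no mentions).  Subgroups: gender, age group, race/ethnicity
    where those columns are present.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")

    def rates(df: pd.DataFrame) -> dict:
        n = len(df)
        mentions = int(df["mention"].sum())
        access = int(df["access"].sum())
        return {
            "n": n,
            "mention_rate": mentions / n if n else float("nan"),
            "access_given_mention": access / mentions if mentions else float("nan"),
        }

    out = {"overall": rates(cohort)}
    for col in ("gender", "age_group", "race_ethnicity"):
        if col in cohort.columns:
            out[col] = {str(level): rates(grp) for level, grp in cohort.groupby(col, observed=True)}
    return out


def _design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded covariate design with the documented reference levels.

    Reference levels: female, <30, White, never-smoker.  Visit counts enter
    linearly.  Complete-case on smoking: rows with smoking == 'missing' are
    dropped by the callers before reaching here.
    """
    cols: dict[str, np.ndarray] = {}
    for cov, levels in CATEGORICAL_LEVELS.items():
        if cov not in cohort.columns:
            continue
        for level in levels[1:]:
            cols[f"{cov}[{level}]"] = (cohort[cov] == level).to_numpy(dtype=float)
    for cov in CONDITION_COLUMNS:
        if cov in cohort.columns:
            cols[cov] = cohort[cov].to_numpy(dtype=float)
    for cov in COUNT_COLUMNS:
        if cov in cohort.columns:
            cols[cov] = cohort[cov].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=cohort.index)
    return sm.add_constant(X, prepend=True)


def _fit_logistic(cohort: pd.DataFrame, outcome: pd.Series, model_name: str) -> pd.DataFrame:
    y = outcome.astype(float)
    if y.nunique() < 2:
        raise ValueError(f"{model_name}: outcome is constant; cannot fit")
    if "smoking" in cohort.columns:
        keep = cohort["smoking"] != "missing"
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("%s: dropping %d records with missing smoking (complete-case)", model_name, n_drop)
        cohort, y = cohort.loc[keep], y.loc[keep]
    X = _design_matrix(cohort)
    model = sm.Logit(y, X)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # non-convergence / singular design
        raise ValueError(f"{model_name}: logistic fit failed ({exc})") from exc
    if not res.mle_retvals.get("converged", False):
        raise ValueError(f"{model_name}: logistic fit did not converge")
    bad = res.bse[res.bse > 50].index.tolist()
    if bad:
        raise ValueError(f"{model_name}: quasi-separation detected for covariates {bad}")
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "term": res.params.index,
            "coef": res.params.to_numpy(),
            "or": np.exp(res.params.to_numpy()),
            "ci_low": np.exp(ci[0].to_numpy()),
            "ci_high": np.exp(ci[1].to_numpy()),
            "p": res.pvalues.to_numpy(),
            "se": res.bse.to_numpy(),
        }
    )
    table.attrs["n"] = int(len(y))
    table.attrs["model"] = model_name
    return table.reset_index(drop=True)


def fit_mention_model(cohort: pd.DataFrame) -> pd.DataFrame:
    """Adjusted logistic model for any firearm mention over the whole cohort."""
    return _fit_logistic(cohort, cohort["mention"], "mention_model")


def fit_access_model(cohort: pd.DataFrame) -> pd.DataFrame:
    """Adjusted logistic model for access, among patients with a mention."""
    sub = cohort.loc[cohort["mention"]]
    if sub.empty:
        raise ValueError("access_model: no patients with a mention")
    return _fit_logistic(sub, sub["access"], "access_model")


def unadjusted_or(cohort: pd.DataFrame, covariate: str, outcome: str = "mention") -> float:
    """Single-covariate logistic OR for a boolean covariate (no adjustment).

    Equals the cross-product ratio of the collapsed 2x2 table; exposed for
    oracle-style consistency checks.
    """
    y = cohort[outcome].astype(float)
    X = sm.add_constant(cohort[covariate].astype(float))
    res = sm.Logit(y, X).fit(disp=0)
    return float(np.exp(res.params[covariate]))
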