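"""Synthetic clinical notes and a synthetic veteran cohort.

Nothing in the real study data is public, so every pipeline stage is
exercised on simulated inputs with the statistical structure the method
assumes:

* **Notes** are built from class-specific templates (positive / negative /
  ambiguous firearm-access language, each with one taxonomy-term slot) and
  distractor templates with no firearm term (emulating term-free PTSD or
  hearing-related documentation).  Templates are embedded in at least 80
  neutral filler words so the 35-word snippet window is exercised on both
  boundary-truncated and interior matches.  The class of a snippet is a
  deterministic function of its template, so gold labels are exact.

* **Cohort** records draw covariates from configurable marginals and the
  mention / access indicators from two logistic data-generating models, so
  the downstream regression can be checked by parameter recovery.  Diagnosis
  events are emitted such that the inpatient/outpatient comorbidity rule
  reconstructs the generated condition flags exactly.

Default marginals and log odds echo the magnitudes seen in national veteran
cohorts (87% male, ~9.5% mention, ~24% access among mentions); they are
study conditions, not tuning knobs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AccessLabel
from .lexicon import Lexicon, find_term_matches

NOTE_CLASSES = ("positive", "negative", "ambiguous", "distractor")

POSITIVE_TEMPLATES = (
    "veteran reports he currently owns a {term} kept at home loaded",
    "patient states she has a {term} in the house with ammunition nearby",
    "endorses ready access to a {term} stored in the bedroom closet",
    "keeps a loaded {term} in his vehicle for personal protection",
    "admits to owning a {term} which is kept unlocked at home",
)

NEGATIVE_TEMPLATES = (
    "veteran denies any current access to a {term} or other weapons",
    "patient reports there is no {term} in the home at this time",
    "denies owning a {term} and denies access to weapons of any kind",
    "states all weapons including the {term} were surrendered to police",
    "no {term} at home per patient and spouse both confirm",
)

AMBIGUOUS_TEMPLATES = (
    "veteran sold his {term} last year to a neighbor",
    "history of {term} fire during deployment overseas was discussed",
    "a {term} remains at his brother's house somewhere else entirely",
    "used to carry a {term} while in the service years ago",
    "mentioned a {term} that may still be in storage out of state",
)

DISTRACTOR_TEMPLATES = (
    "combat exposure with artillery noise during deployment reviewed for documentation",
    "hearing loss attributed to blast exposure in theater was evaluated today",
    "nightmares about convoy incidents discussed during therapy session this week",
    "screening for depression completed and results reviewed with the patient",
)

_TEMPLATES: dict[str, tuple[str, ...]] = {
    "positive": POSITIVE_TEMPLATES,
    "negative": NEGATIVE_TEMPLATES,
    "ambiguous": AMBIGUOUS_TEMPLATES,
    "distractor": DISTRACTOR_TEMPLATES,
}

# Neutral clinical filler; deliberately free of taxonomy terms and of the
# class cue words (owns / denies / sold / access ...) used in templates.
_FILLER_WORDS = (
    "blood pressure stable medication list reviewed follow up in clinic "
    "vital signs within normal limits continue current plan diet and exercise "
    "sleep adequate mood euthymic affect congruent no acute distress noted "
    "appointment scheduled labs ordered results pending chart updated "
    "allergies unchanged immunizations current gait steady lungs clear "
    "heart regular rate rhythm abdomen soft nontender extremities warm"
).split()

CLINICS = ("primary", "urgent", "emergency", "mental_health", "other")


@dataclass(frozen=True)
class NoteTemplateBank:
    templates: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: dict(_TEMPLATES))
    term_pool: Lexicon = field(default_factory=Lexicon.default)

    def __post_init__(self) -> None:
        for cls in ("positive", "negative", "ambiguous"):
            for t in self.templates.get(cls, ()):
                if t.count("{term}") != 1:
                    raise ValueError(f"{cls} template must contain exactly one {{term}} slot: {t!r}")
        for t in self.templates.get("distractor", ()):
            if find_term_matches(t, self.term_pool):
                raise ValueError(f"distractor template contains a taxonomy term: {t!r}")


def generate_note(
    label: str,
    bank: NoteTemplateBank,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """One synthetic note of the requested class; returns (text, gold label).

    The instantiated template is surrounded by >=80 filler words; the number
    of leading filler words varies from 0 to ~70 so keyphrase windows are
    truncated at the note start in some notes and interior in others.
    """
    if label not in NOTE_CLASSES:
        raise ValueError(f"unknown note class: {label!r}")
    templates = bank.templates.get(label, ())
    if not templates:
        raise ValueError(f"template bank has no templates for class {label!r}")
    template = templates[rng.integers(len(templates))]
    if label == "distractor":
        sentence = template
    else:
        term = " ".join(bank.term_pool.terms[rng.integers(len(bank.term_pool))])
        sentence = template.format(term=term)
    n_before = int(rng.integers(0, 71))
    n_after = 85 - n_before + int(rng.integers(0, 21))
    before = rng.choice(_FILLER_WORDS, size=n_before)
    after = rng.choice(_FILLER_WORDS, size=n_after)
    text = " ".join([*before, sentence, *after])
    return text, label


def generate_corpus(
    n: int,
    class_mix: Sequence[float] = (0.25, 0.35, 0.15, 0.25),
    seed: int = 0,
    bank: NoteTemplateBank | None = None,
) -> tuple[list[dict], pd.DataFrame]:
    """A corpus of n synthetic notes with gold note-class labels.

    `class_mix` gives the multinomial probabilities for (positive, negative,
    ambiguous, distractor).  Returns (note records, gold DataFrame); records
    carry note_id, patient_id, date, clinic and text, ready for JSONL.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (4,) or not math.isclose(mix.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("class_mix must be 4 probabilities summing to 1")
    bank = bank or NoteTemplateBank()
    rng = np.random.default_rng(seed)
    classes = rng.choice(NOTE_CLASSES, size=n, p=mix)
    records, gold = [], []
    for i, cls in enumerate(classes):
        text, label = generate_note(str(cls), bank, rng)
        date = f"{2012 + int(rng.integers(0, 6))}-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}"
        records.append(
            {
                "note_id": f"note{i:06d}",
                "patient_id": f"pt{int(rng.integers(0, max(1, n // 2))):06d}",
                "date": date,
                "clinic": str(rng.choice(CLINICS)),
                "text": text,
            }
        )
        gold.append({"note_id": f"note{i:06d}", "gold_label": label})
    return records, pd.DataFrame(gold)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Illustrative diagnosis code sets (toy values for simulation and tests;
#: real analyses must supply validated groupings).
TOY_CODE_SETS: dict[str, set[str]] = {
    "mdd": {"296.20", "F32.9"},
    "ptsd": {"309.81", "F43.10"},
    "bipolar": {"296.40", "F31.9"},
    "oud": {"304.00", "F11.20"},
    "alcohol": {"303.90", "F10.20"},
    "drug": {"304.90", "F19.20"},
    "chronic_pain": {"338.29", "G89.29"},
}

_DEF_MENTION_LOG_ODDS: dict[str, float] = {
    "intercept": -2.96,
    "gender[male]": math.log(1.45),
    "age_group[30-49]": math.log(0.88),
    "age_group[50+]": math.log(0.61),
    "race_ethnicity[Black]": math.log(1.04),
    "race_ethnicity[Hispanic]": math.log(0.96),
    "race_ethnicity[Other]": math.log(1.02),
    "mdd": math.log(1.43),
    "ptsd": math.log(2.24),
    "smoking[past]": math.log(1.08),
    "smoking[current]": math.log(0.99),
    "chronic_pain": math.log(1.06),
    "tbi": math.log(1.04),
    "mst": math.log(0.91),
    "bipolar": math.log(1.09),
    "oud": math.log(1.08),
    "alcohol": math.log(1.18),
    "drug": math.log(0.96),
    "ed_visits": math.log(1.03),
    "mh_visits": math.log(1.03),
}

_DEF_ACCESS_LOG_ODDS: dict[str, float] = {
    "intercept": -1.23,
    "gender[male]": math.log(1.19),
    "age_group[30-49]": math.log(0.99),
    "age_group[50+]": math.log(0.89),
    "race_ethnicity[Black]": math.log(0.73),
    "race_ethnicity[Hispanic]": math.log(0.72),
    "race_ethnicity[Other]": math.log(0.84),
    "mdd": math.log(1.25),
    "ptsd": math.log(1.25),
    "smoking[past]": math.log(1.05),
    "smoking[current]": math.log(1.11),
    "chronic_pain": math.log(1.03),
    "tbi": math.log(0.99),
    "mst": math.log(0.92),
    "bipolar": math.log(0.95),
    "oud": math.log(1.01),
    "alcohol": math.log(1.10),
    "drug": math.log(0.80),
    "ed_visits": math.log(0.99),
    "mh_visits": 0.0,
}


@dataclass(frozen=True)
class CohortGeneratorSpec:
    n: int = 20_000
    seed: int = 0
    gender: Mapping[str, float] = field(default_factory=lambda: {"female": 0.1307, "male": 0.8693})
    age_group: Mapping[str, float] = field(
        default_factory=lambda: {"<30": 0.1167, "30-49": 0.6823, "50+": 0.2010}
    )
    race_ethnicity: Mapping[str, float] = field(
        default_factory=lambda: {"White": 0.6353, "Black": 0.1783, "Hispanic": 0.1165, "Other": 0.0699}
    )
    smoking: Mapping[str, float] = field(
        default_factory=lambda: {"never": 0.3908, "past": 0.4197, "current": 0.1395, "missing": 0.05}
    )
    condition_prev: Mapping[str, float] = field(
        default_factory=lambda: {
            "mdd": 0.233,
            "ptsd": 0.431,
            "bipolar": 0.039,
            "oud": 0.331,
            "alcohol": 0.102,
            "drug": 0.104,
            "chronic_pain": 0.098,
            "tbi": 0.899,
            "mst": 0.917,
        }
    )
    ed_visit_mean: float = 0.32
    mh_visit_mean: float = 3.5
    mention_log_odds: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_MENTION_LOG_ODDS))
    access_log_odds: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_ACCESS_LOG_ODDS))

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        for name in ("gender", "age_group", "race_ethnicity", "smoking"):
            marg = getattr(self, name)
            if not math.isclose(sum(marg.values()), 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} marginals must sum to 1")
            if any(not 0.0 < p < 1.0 for p in marg.values()):
                raise ValueError(f"{name} marginal probabilities must be in (0, 1)")
        for cond, p in self.condition_prev.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"condition prevalence for {cond} must be in (0, 1)")


def _sample_categorical(rng: np.random.Generator, marg: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(marg)
    p = np.asarray([marg[l] for l in levels], dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


def _linear_predictor(cohort: pd.DataFrame, log_odds: Mapping[str, float]) -> np.ndarray:
    """Evaluate intercept + sum of per-covariate log-OR contributions.

    Keys use the design-matrix naming: "gender[male]" is an indicator for
    that level; bare names are booleans or counts entering linearly.
    Records with missing smoking sit at the smoking reference level.
    """
    eta = np.full(len(cohort), log_odds.get("intercept", 0.0), dtype=float)
    for key, beta in log_odds.items():
        if key == "intercept" or beta == 0.0:
            continue
        if "[" in key:
            col, level = key[:-1].split("[", 1)
            eta += beta * (cohort[col] == level).to_numpy(dtype=float)
        else:
            eta += beta * cohort[key].to_numpy(dtype=float)
    return eta


def generate_cohort(
    spec: CohortGeneratorSpec = CohortGeneratorSpec(),
    with_events: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a synthetic cohort and (optionally) its diagnosis events.

    Covariates are drawn independently from the marginals; mention ~
    Bernoulli(logistic(eta_mention)); access is drawn only where mention is
    true, from the access model.  Events are emitted so that the
    inpatient/outpatient rule reconstructs each generated condition flag
    exactly: a flagged condition gets one inpatient code or two
    separate-day outpatient codes; an unflagged condition gets no events or
    a single non-qualifying outpatient code.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    cohort = pd.DataFrame(
        {
            "patient_id": [f"p{i:07d}" for i in range(n)],
            "gender": _sample_categorical(rng, spec.gender, n),
            "age_group": _sample_categorical(rng, spec.age_group, n),
            "race_ethnicity": _sample_categorical(rng, spec.race_ethnicity, n),
            "smoking": _sample_categorical(rng, spec.smoking, n),
            "ed_visits": rng.poisson(spec.ed_visit_mean, size=n),
            "mh_visits": rng.poisson(spec.mh_visit_mean, size=n),
        }
    )
    for cond, p in spec.condition_prev.items():
        cohort[cond] = rng.random(n) < p

    eta_m = _linear_predictor(cohort, spec.mention_log_odds)
    cohort["mention"] = rng.random(n) < 1.0 / (1.0 + np.exp(-eta_m))
    eta_a = _linear_predictor(cohort, spec.access_log_odds)
    access = rng.random(n) < 1.0 / (1.0 + np.exp(-eta_a))
    cohort["access"] = cohort["mention"] & access

    if not with_events:
        return cohort, pd.DataFrame(
            columns=["patient_id", "code", "code_system", "setting", "date"]
        )

    events: list[tuple[str, str, str, str, str]] = []
    coded = [c for c in spec.condition_prev if c in TOY_CODE_SETS]
    for cond in coded:
        codes = sorted(TOY_CODE_SETS[cond])
        flagged = np.flatnonzero(cohort[cond].to_numpy())
        unflagged = np.flatnonzero(~cohort[cond].to_numpy())
        inpt = rng.random(flagged.size) < 0.3
        for idx, use_inpt in zip(flagged, inpt):
            pid = cohort.at[idx, "patient_id"]
            code = codes[int(rng.integers(len(codes)))]
            system = "ICD9" if code[0].isdigit() else "ICD10"
            day = int(rng.integers(1, 28))
            if use_inpt:
                events.append((pid, code, system, "inpatient", f"2015-03-{day:02d}"))
            else:
                events.append((pid, code, system, "outpatient", f"2015-03-{day:02d}"))
                events.append((pid, code, system, "outpatient", f"2015-04-{day:02d}"))
        # Non-qualifying noise: one outpatient code for ~10% of unflagged.
        noisy = unflagged[rng.random(unflagged.size) < 0.1]
        for idx in noisy:
            pid = cohort.at[idx, "patient_id"]
            code = codes[int(rng.integers(len(codes)))]
            system = "ICD9" if code[0].isdigit() else "ICD10"
            events.append((pid, code, system, "outpatient", f"2015-05-{int(rng.integers(1, 28)):02d}"))
    events_df = pd.DataFrame(events, columns=["patient_id", "code", "code_system", "setting", "date"])
    return cohort, events_df


def gold_access_label(note_class: str) -> AccessLabel | None:
    """Map a generated note class to its snippet-level gold label."""
    if note_class == "distractor":
        return None
    return AccessLabel(note_class)
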