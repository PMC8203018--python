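"""Reference summary figures from the original development study.

The tool was developed against a national veteran cohort whose notes are not
public; what survives in print are summary figures: the validation-set
composition and rounded sensitivity/specificity, and the cohort cross-tab of
documentation status by covariates.  This module ships those printed numbers
as structured data so the derived quantities (accuracy, PPV, mention and
access proportions) can be *recomputed* from them rather than quoted.

The 50+ age row's no-documentation count is derived from the column total
(the printed cell is inconsistent with its own column and duplicates the
row's documented total — a typesetting artifact); the derived value carries
the printed 20.1% column share.
"""

from __future__ import annotations

import pandas as pd

from .metrics import ConfusionMatrix, compute_metrics, find_confusion_matrix

#: Note-level validation set: 238 notes, 63 positive and 175 negative for
#: firearm access, with rounded published sensitivity and specificity.
VALIDATION_N_POSITIVE = 63
VALIDATION_N_NEGATIVE = 175
VALIDATION_SENSITIVITY_PCT = 57.1
VALIDATION_SPECIFICITY_PCT = 90.9

#: Documentation status counts by covariate level:
#: (no documentation, documentation without access, documentation with access).
DOCUMENTATION_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "gender": {
        "female": (90_282, 5_451, 1_440),
        "male": (600_398, 49_221, 16_161),
    },
    "age_group": {
        "<30": (80_598, 6_116, 1_927),
        "30-49": (471_218, 41_083, 13_515),
        "50+": (138_783, 7_467, 2_156),  # no-doc cell derived from column total
    },
}


def validation_confusion_matrix() -> ConfusionMatrix:
    """Invert the published rounded metrics to the unique integer 2x2 matrix.

    Raises if the search does not return exactly one candidate (it does:
    rounding sensitivity/specificity to one decimal pins tp and tn).
    """
    candidates = find_confusion_matrix(
        VALIDATION_N_POSITIVE,
        VALIDATION_N_NEGATIVE,
        VALIDATION_SENSITIVITY_PCT,
        VALIDATION_SPECIFICITY_PCT,
    )
    if len(candidates) != 1:
        raise RuntimeError(f"expected a unique confusion matrix, found {len(candidates)}")
    return candidates[0]


def reference_cohort_margins() -> pd.DataFrame:
    """The published cross-tab as a tidy DataFrame (one row per level)."""
    rows = []
    for cov, levels in DOCUMENTATION_COUNTS.items():
        for level, (no_doc, doc_no_access, doc_access) in levels.items():
            rows.append(
                {
                    "covariate": cov,
                    "level": level,
                    "no_documentation": no_doc,
                    "documentation_no_access": doc_no_access,
                    "documentation_access": doc_access,
                }
            )
    return pd.DataFrame(rows)


def mention_rate(no_doc: int, doc_no_access: int, doc_access: int) -> float:
    """Share of patients with any firearm-term documentation."""
    documented = doc_no_access + doc_access
    return documented / (no_doc + documented)


def access_given_mention(doc_no_access: int, doc_access: int) -> float:
    """Share classified access-positive among those with any documentation."""
    return doc_access / (doc_no_access + doc_access)
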