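"""Double annotation of snippets: labels, adjudication, and agreement.

Each snippet is labelled by two annotators as POSITIVE (current access to at
least one firearm is documented), NEGATIVE (documented no current access) or
AMBIGUOUS (insufficient evidence, e.g. a firearm owned but stored elsewhere).
Disagreements are resolved by consensus adjudication; Cohen's kappa
quantifies chance-corrected inter-annotator agreement.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .lexicon import Snippet


class AccessLabel(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    AMBIGUOUS = "ambiguous"

    @classmethod
    def parse(cls, value: "str | AccessLabel") -> "AccessLabel":
        if isinstance(value, AccessLabel):
            return value
        return cls(value.strip().lower())


#: Binary collapse used for note-level evaluation: AMBIGUOUS counts as
#: not-positive alongside NEGATIVE.
def collapse_binary(label: AccessLabel) -> AccessLabel:
    return AccessLabel.POSITIVE if label is AccessLabel.POSITIVE else AccessLabel.NEGATIVE


@dataclass(frozen=True)
class AnnotatedSnippet:
    snippet: Snippet
    label_a: AccessLabel
    label_b: AccessLabel
    consensus: AccessLabel

    def __post_init__(self) -> None:
        if self.label_a is self.label_b and self.consensus is not self.label_a:
            raise ValueError("consensus must equal the agreed label when annotators agree")


def adjudicate(
    a: AccessLabel,
    b: AccessLabel,
    tie_break: AccessLabel | None = None,
) -> AccessLabel:
    """Resolve a pair of annotator labels into the reference label.

    Agreement stands on its own; a disagreement requires an explicit
    adjudicated label — there is no silent default.
    """
    a, b = AccessLabel.parse(a), AccessLabel.parse(b)
    if a is b:
        return a
    if tie_break is None:
        raise ValueError(
            f"annotators disagree ({a.value} vs {b.value}) and no adjudicated label was supplied"
        )
    return AccessLabel.parse(tie_break)


def cohen_kappa(labels_a: Sequence[AccessLabel | str], labels_b: Sequence[AccessLabel | str]) -> float:
    """Cohen's kappa between two annotators: (p_o − p_e) / (1 − p_e).

    Expected agreement p_e comes from the per-annotator marginal label
    frequencies.  When both annotators are constant and identical (p_e = 1),
    agreement is perfect and kappa is defined as 1.0.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    if not labels_a:
        raise ValueError("label vectors must be non-empty")
    a = [AccessLabel.parse(x) for x in labels_a]
    b = [AccessLabel.parse(x) for x in labels_b]
    n = len(a)
    p_o = sum(x is y for x, y in zip(a, b)) / n
    freq_a, freq_b = Counter(a), Counter(b)
    p_e = sum(freq_a[k] * freq_b[k] for k in set(freq_a) | set(freq_b)) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def read_annotations(path: str) -> pd.DataFrame:
    """Read an annotation CSV (snippet_id, annotator_a, annotator_b[, consensus]).

    The consensus column is filled by adjudication where the annotators
    agree; rows with disagreement must carry an explicit consensus.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"snippet_id", "annotator_a", "annotator_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    if "consensus" not in df.columns:
        df["consensus"] = None
    out = []
    for row in df.itertuples(index=False):
        tie = None
        if isinstance(row.consensus, str) and row.consensus.strip():
            tie = AccessLabel.parse(row.consensus)
        out.append(adjudicate(row.annotator_a, row.annotator_b, tie).value)
    df["consensus"] = out
    return df
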