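"""Binary classification metrics and the reported-metric reconstruction.

Note-level validation is binary (positive for firearm access vs not), so
performance is summarised by the usual 2x2 confusion-matrix quantities:
accuracy, sensitivity, specificity, PPV and NPV.  `find_confusion_matrix`
inverts rounded published sensitivity/specificity back to the integer
confusion matrix they came from, which lets derived metrics (accuracy, PPV)
be recomputed exactly from printed summary figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


def _ratio(num: int, den: int) -> float:
    """num/den, or NaN when the denominator is zero (metric undefined)."""
    return num / den if den else math.nan


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, truth: Sequence[bool], pred: Sequence[bool]) -> "ConfusionMatrix":
        if len(truth) != len(pred):
            raise ValueError("label vectors must have equal length")
        pairs = list(zip(truth, pred))
        return cls(
            tp=sum(t and p for t, p in pairs),
            fp=sum((not t) and p for t, p in pairs),
            tn=sum((not t) and (not p) for t, p in pairs),
            fn=sum(t and (not p) for t, p in pairs),
        )


@dataclass(frozen=True)
class EvalMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def compute_metrics(cm: ConfusionMatrix) -> EvalMetrics:
    """Accuracy, sensitivity, specificity, PPV, NPV from a 2x2 matrix.

    Metrics with a zero denominator are NaN, never silently 0.  An all-zero
    matrix is an error (nothing was classified).
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return EvalMetrics(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
    )


def round_percent(x: float, ndigits: int = 1) -> float:
    """Half-up rounding of a proportion expressed in percent."""
    scale = 10**ndigits
    return math.floor(x * 100 * scale + 0.5) / scale


def find_confusion_matrix(
    n_positive: int,
    n_negative: int,
    sensitivity_pct: float,
    specificity_pct: float,
    ndigits: int = 1,
) -> list[ConfusionMatrix]:
    """All integer 2x2 matrices consistent with rounded published metrics.

    Enumerates tp in 0..n_positive and tn in 0..n_negative and keeps the
    matrices whose sensitivity and specificity round (half-up, `ndigits`
    decimals in percent) to the published values.  With a unique solution
    the derived accuracy and PPV are exactly recoverable.
    """
    out = []
    for tp in range(n_positive + 1):
        if round_percent(tp / n_positive, ndigits) != sensitivity_pct:
            continue
        for tn in range(n_negative + 1):
            if round_percent(tn / n_negative, ndigits) == specificity_pct:
                out.append(
                    ConfusionMatrix(tp=tp, fp=n_negative - tn, tn=tn, fn=n_positive - tp)
                )
    return out
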