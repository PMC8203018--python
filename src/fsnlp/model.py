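"""Random-forest snippet classifier and note-level label aggregation.

The classifier is a 200-tree random forest (max depth 15, gini splits)
trained on binary n-gram indicators plus the keyphrase offset.  Notes are
labelled by classifying every snippet they contain and aggregating with
any-positive precedence; a note with no taxonomy match is NO_MENTION.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .annotation import AccessLabel, collapse_binary
from .features import VocabularySpec, featurize, feature_matrix
from .lexicon import DEFAULT_WINDOW, Lexicon, Snippet, extract_all_snippets


class NoteLabel(str, enum.Enum):
    NO_MENTION = "no_mention"
    POSITIVE = "positive"
    NEGATIVE = "negative"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ClassifierConfig:
    n_estimators: int = 200
    max_depth: int = 15
    split_criterion: str = "gini"
    train_fraction: float = 0.85
    seed: int = 0
    label_scheme: Literal["binary", "ternary"] = "ternary"
    vocab_scope: Literal["train", "all"] = "train"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass
class AccessClassifier:
    """Fitted model handle pairing the forest with its vocabulary and config."""

    forest: RandomForestClassifier
    vocab: VocabularySpec
    config: ClassifierConfig

    def predict_snippet(self, snippet: Snippet) -> AccessLabel:
        x = featurize(snippet, self.vocab).dense().reshape(1, -1)
        return AccessLabel(self.forest.predict(x)[0])

    def predict_many(self, snippets: Sequence[Snippet]) -> list[AccessLabel]:
        if not snippets:
            return []
        x = feature_matrix(snippets, self.vocab)
        return [AccessLabel(v) for v in self.forest.predict(x)]


def _apply_scheme(labels: Sequence[AccessLabel], scheme: str) -> list[AccessLabel]:
    if scheme == "binary":
        return [collapse_binary(l) for l in labels]
    return list(labels)


def train_classifier(
    snippets: Sequence[Snippet],
    labels: Sequence[AccessLabel],
    vocab: VocabularySpec,
    config: ClassifierConfig = ClassifierConfig(),
) -> AccessClassifier:
    """Fit the seeded random forest on featurized snippets.

    Raises ValueError when fewer than two distinct labels remain under the
    configured label scheme (a one-class forest cannot discriminate).
    """
    if len(snippets) != len(labels):
        raise ValueError("snippets and labels must have equal length")
    y = [l.value for l in _apply_scheme([AccessLabel.parse(l) for l in labels], config.label_scheme)]
    present = set(y)
    if len(present) < 2:
        universe = (
            {AccessLabel.POSITIVE.value, AccessLabel.NEGATIVE.value}
            if config.label_scheme == "binary"
            else {l.value for l in AccessLabel}
        )
        missing = sorted(universe - present)
        raise ValueError(f"training labels contain a single class; missing: {missing}")
    forest = RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        criterion=config.split_criterion,
        random_state=config.seed,
    )
    forest.fit(feature_matrix(snippets, vocab), y)
    return AccessClassifier(forest=forest, vocab=vocab, config=config)


def aggregate_snippet_labels(labels: Sequence[AccessLabel]) -> NoteLabel:
    """Note label from snippet labels: any POSITIVE wins, then any NEGATIVE,
    else AMBIGUOUS; no snippets means NO_MENTION."""
    if not labels:
        return NoteLabel.NO_MENTION
    if AccessLabel.POSITIVE in labels:
        return NoteLabel.POSITIVE
    if AccessLabel.NEGATIVE in labels:
        return NoteLabel.NEGATIVE
    return NoteLabel.AMBIGUOUS


def classify_note(
    text: str,
    lexicon: Lexicon,
    classifier: AccessClassifier,
    window: int = DEFAULT_WINDOW,
    note_id: str = "",
) -> NoteLabel:
    """Label one note: match terms, classify each snippet, aggregate."""
    snippets = extract_all_snippets(text, lexicon, note_id=note_id, window=window)
    return aggregate_snippet_labels(classifier.predict_many(snippets))
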