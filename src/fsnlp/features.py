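"""Thresholded n-gram vocabulary and binary snippet featurization.

Features are binary indicators for the presence of vocabulary unigrams and
adjacent-token bigrams in a snippet, plus the token offset of the keyphrase
within the snippet.  Frequency thresholds (unigrams must occur more than 34
times, bigrams more than 4 times in the fitting corpus) drop rare n-grams to
limit overfitting.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lexicon import Snippet

logger = logging.getLogger(__name__)

DEFAULT_MIN_UNIGRAM = 35  # "frequency greater than 34"
DEFAULT_MIN_BIGRAM = 5  # "frequency greater than four"


@dataclass(frozen=True)
class VocabularySpec:
    """Ordered (lexicographic) n-gram vocabulary with its fitting thresholds."""

    unigrams: tuple[str, ...]
    bigrams: tuple[tuple[str, str], ...]
    min_unigram_count: int = DEFAULT_MIN_UNIGRAM
    min_bigram_count: int = DEFAULT_MIN_BIGRAM

    def __post_init__(self) -> None:
        if list(self.unigrams) != sorted(self.unigrams):
            raise ValueError("unigrams must be lexicographically ordered")
        if list(self.bigrams) != sorted(self.bigrams):
            raise ValueError("bigrams must be lexicographically ordered")

    def __len__(self) -> int:
        return len(self.unigrams) + len(self.bigrams)

    @property
    def feature_names(self) -> list[str]:
        """Indicator names in index order; bigram tokens joined with '_'."""
        return list(self.unigrams) + ["_".join(b) for b in self.bigrams]


@dataclass(frozen=True)
class FeatureVector:
    indicators: np.ndarray  # binary, length |unigrams|+|bigrams|
    keyphrase_offset: int

    def dense(self) -> np.ndarray:
        """Indicators with the keyphrase offset appended as the last column."""
        return np.concatenate([self.indicators, [self.keyphrase_offset]]).astype(float)


def build_vocabulary(
    snippets: Sequence[Snippet],
    min_unigram: int = DEFAULT_MIN_UNIGRAM,
    min_bigram: int = DEFAULT_MIN_BIGRAM,
) -> VocabularySpec:
    """Count n-grams pooled over snippets and keep those meeting the thresholds.

    Bigrams are adjacent token pairs *within* a snippet; no pair spans two
    snippets.  Ordering is lexicographic so feature indices are stable across
    runs and machines.
    """
    uni: Counter[str] = Counter()
    bi: Counter[tuple[str, str]] = Counter()
    for s in snippets:
        uni.update(s.tokens)
        bi.update(zip(s.tokens, s.tokens[1:]))
    if not snippets:
        logger.warning("build_vocabulary called with no snippets; vocabulary is empty")
    return VocabularySpec(
        unigrams=tuple(sorted(t for t, c in uni.items() if c >= min_unigram)),
        bigrams=tuple(sorted(p for p, c in bi.items() if c >= min_bigram)),
        min_unigram_count=min_unigram,
        min_bigram_count=min_bigram,
    )


def featurize(snippet: Snippet, vocab: VocabularySpec) -> FeatureVector:
    """Binary presence indicators for each vocabulary n-gram in the snippet."""
    present_uni = set(snippet.tokens)
    present_bi = set(zip(snippet.tokens, snippet.tokens[1:]))
    indicators = np.fromiter(
        (int(u in present_uni) for u in vocab.unigrams),
        dtype=np.int8,
        count=len(vocab.unigrams),
    )
    bi_ind = np.fromiter(
        (int(b in present_bi) for b in vocab.bigrams),
        dtype=np.int8,
        count=len(vocab.bigrams),
    )
    return FeatureVector(
        indicators=np.concatenate([indicators, bi_ind]),
        keyphrase_offset=snippet.keyphrase_offset,
    )


def feature_matrix(snippets: Sequence[Snippet], vocab: VocabularySpec) -> np.ndarray:
    """Stack featurized snippets into an (n, |vocab|+1) design matrix."""
    return np.vstack([featurize(s, vocab).dense() for s in snippets])


def split_train_test(
    records: Sequence,
    labels: Sequence,
    train_fraction: float = 0.85,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Seeded, label-stratified index split with train size round(n·f).

    Per-class train counts are allocated proportionally with largest
    remainders so the total is exactly round(n·f).  A class with fewer than
    2 members triggers an unstratified fallback with a warning.  Returns
    (train_indices, test_indices); the two lists partition range(n).
    """
    if len(records) != len(labels):
        raise ValueError("records and labels must have equal length")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(n * train_fraction + 0.5))

    by_class: dict[object, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)

    if any(len(v) < 2 for v in by_class.values()):
        logger.warning("a class has <2 members; falling back to an unstratified split")
        perm = rng.permutation(n)
        return sorted(perm[:n_train].tolist()), sorted(perm[n_train:].tolist())

    # Largest-remainder allocation of n_train across classes.
    classes = sorted(by_class, key=str)
    exact = {c: len(by_class[c]) * train_fraction for c in classes}
    alloc = {c: int(np.floor(exact[c])) for c in classes}
    short = n_train - sum(alloc.values())
    for c in sorted(classes, key=lambda c: (-(exact[c] - alloc[c]), str(c)))[:short]:
        alloc[c] += 1

    train: list[int] = []
    test: list[int] = []
    for c in classes:
        idx = np.array(by_class[c])
        perm = rng.permutation(len(idx))
        train.extend(idx[perm[: alloc[c]]].tolist())
        test.extend(idx[perm[alloc[c] :]].tolist())
    return sorted(train), sorted(test)
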