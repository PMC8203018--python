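"""Firearm taxonomy, tokenization, term matching and snippet extraction.

The unit of analysis downstream is the *snippet*: a window of up to 35 words
on each side of a matched taxonomy phrase (the *keyphrase*).  Everything in
this module works on lowercase alphanumeric tokens with character spans back
into the source text, so matches and snippets are auditable against the raw
note.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 35

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

# Digit+unit fusions ("9mm", "12gauge") are split into two tokens so that the
# spaced phrase forms in the taxonomy ("9 mm glock") match fused clinical
# spellings.  Only these measurement units are split; generic digit/letter
# boundaries (e.g. "m1") are left intact.
_UNIT_SPLIT_RE = re.compile(r"^(\d+)(mm|gauge|caliber|magnum)$")


@dataclass(frozen=True)
class TokenizedText:
    """Lowercase alphanumeric tokens plus per-token half-open char spans."""

    tokens: tuple[str, ...]
    spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.spans):
            raise ValueError("tokens and spans must have equal length")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Lexicon:
    """An ordered set of firearm phrases, each a tuple of lowercase tokens."""

    terms: tuple[tuple[str, ...], ...]
    source_label: str = "default"

    def __post_init__(self) -> None:
        seen: set[tuple[str, ...]] = set()
        for term in self.terms:
            if not term:
                raise ValueError("lexicon phrases must have at least one token")
            for tok in term:
                if not tok or not re.fullmatch(r"[a-z0-9]+", tok):
                    raise ValueError(f"invalid lexicon token: {tok!r}")
            if term in seen:
                raise ValueError(f"duplicate lexicon phrase: {' '.join(term)}")
            seen.add(term)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[tuple[str, ...]]:
        return iter(self.terms)

    @classmethod
    def from_phrases(cls, phrases: Iterable[str], source_label: str = "custom") -> "Lexicon":
        terms = tuple(tuple(tokenize(p).tokens) for p in phrases)
        return cls(terms=terms, source_label=source_label)

    @classmethod
    def from_file(cls, path: str | Path) -> "Lexicon":
        """Read a term file: UTF-8, one phrase per line, '#' comments."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        phrases = [ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
        return cls.from_phrases(phrases, source_label=str(path))

    @classmethod
    def default(cls) -> "Lexicon":
        """The 27-phrase firearm taxonomy shipped with the package."""
        text = resources.files("fsnlp.data").joinpath("firearm_terms.txt").read_text("utf-8")
        phrases = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
        return cls.from_phrases(phrases, source_label="builtin:firearm_terms.txt")


@dataclass(frozen=True)
class TermMatch:
    """One occurrence of a lexicon phrase in a note, in token coordinates."""

    note_id: str
    term: tuple[str, ...]
    token_start: int
    token_end: int  # exclusive
    char_span: tuple[int, int]

    @property
    def term_text(self) -> str:
        return " ".join(self.term)


@dataclass(frozen=True)
class Snippet:
    """A keyphrase-anchored token window, the classifier's unit of input."""

    snippet_id: str
    note_id: str
    tokens: tuple[str, ...]
    keyphrase_offset: int
    keyphrase_len: int
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if len(self.tokens) > 2 * self.window + self.keyphrase_len:
            raise ValueError("snippet longer than 2*window + keyphrase length")
        if not (0 <= self.keyphrase_offset <= len(self.tokens) - self.keyphrase_len):
            raise ValueError("keyphrase offset out of range")

    @property
    def keyphrase(self) -> tuple[str, ...]:
        return self.tokens[self.keyphrase_offset : self.keyphrase_offset + self.keyphrase_len]


def tokenize(text: str) -> TokenizedText:
    """Split text into lowercase alphanumeric tokens with source spans.

    Maximal runs of [A-Za-z0-9] become tokens (lowercased); every other
    character is a separator.  Digit+unit fusions such as "9mm" are split
    into ("9", "mm") with sub-spans so spaced taxonomy phrases still match.
    """
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(0).lower()
        fused = _UNIT_SPLIT_RE.match(tok)
        if fused:
            digits, unit = fused.group(1), fused.group(2)
            tokens.append(digits)
            spans.append((m.start(), m.start() + len(digits)))
            tokens.append(unit)
            spans.append((m.start() + len(digits), m.end()))
        else:
            tokens.append(tok)
            spans.append((m.start(), m.end()))
    return TokenizedText(tokens=tuple(tokens), spans=tuple(spans))


def find_term_matches(text: str, lexicon: Lexicon, note_id: str = "") -> list[TermMatch]:
    """Locate lexicon phrases in text at token boundaries, case-insensitively.

    Overlapping candidates are resolved longest-match-first, then leftmost
    ("sniper rifle" suppresses the inner "rifle"); the surviving matches are
    returned in document order and never overlap in token space.
    """
    tk = tokenize(text)
    candidates: list[tuple[int, int, tuple[str, ...]]] = []
    for term in lexicon:
        k = len(term)
        for i in range(len(tk.tokens) - k + 1):
            if tk.tokens[i : i + k] == term:
                candidates.append((i, i + k, term))
    return _resolve_overlaps(candidates, tk, note_id)


def _resolve_overlaps(
    candidates: Sequence[tuple[int, int, tuple[str, ...]]],
    tk: TokenizedText,
    note_id: str,
) -> list[TermMatch]:
    taken: list[tuple[int, int]] = []
    accepted: list[tuple[int, int, tuple[str, ...]]] = []
    for start, end, term in sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0])):
        if all(end <= s or start >= e for s, e in taken):
            taken.append((start, end))
            accepted.append((start, end, term))
    accepted.sort(key=lambda c: c[0])
    return [
        TermMatch(
            note_id=note_id,
            term=term,
            token_start=start,
            token_end=end,
            char_span=(tk.spans[start][0], tk.spans[end - 1][1]),
        )
        for start, end, term in accepted
    ]


def count_term_frequencies(
    corpus: Iterable[Mapping[str, object]],
    lexicon: Lexicon,
) -> tuple[dict[str, int], int]:
    """Occurrence counts per taxonomy phrase over a corpus of note records.

    Counts are raw occurrence counts (not distinct by patient or note).
    Every lexicon phrase appears in the result, zero-count phrases included.
    Returns (counts, number of skipped records); unreadable records are
    skipped with a logged warning.
    """
    counts: dict[str, int] = {" ".join(t): 0 for t in lexicon}
    skipped = 0
    for record in corpus:
        try:
            text = str(record["text"])
            note_id = str(record.get("note_id", ""))
        except (TypeError, KeyError) as exc:
            logger.warning("skipping unreadable note record: %s", exc)
            skipped += 1
            continue
        for m in find_term_matches(text, lexicon, note_id=note_id):
            counts[m.term_text] += 1
    return counts, skipped


def extract_snippet(
    text: str,
    match: TermMatch,
    window: int = DEFAULT_WINDOW,
    snippet_id: str | None = None,
) -> Snippet:
    """Cut the up-to-`window`-words-each-side token window around a match.

    The window truncates at note boundaries; the keyphrase offset inside the
    snippet is recorded so the classifier can use keyphrase position as a
    feature.  Raises ValueError if the match does not fit the text (stale
    match from a different note revision).
    """
    tk = tokenize(text)
    start, end = match.token_start, match.token_end
    if end > len(tk.tokens) or tk.tokens[start:end] != match.term:
        raise ValueError(
            f"stale match: term {match.term_text!r} not found at tokens {start}:{end}"
        )
    lo = max(0, start - window)
    hi = min(len(tk.tokens), end + window)
    return Snippet(
        snippet_id=snippet_id or f"{match.note_id}:{start}",
        note_id=match.note_id,
        tokens=tk.tokens[lo:hi],
        keyphrase_offset=start - lo,
        keyphrase_len=end - start,
        window=window,
    )


def extract_all_snippets(
    text: str,
    lexicon: Lexicon,
    note_id: str = "",
    window: int = DEFAULT_WINDOW,
) -> list[Snippet]:
    """Find every taxonomy match in a note and cut one snippet per match."""
    return [
        extract_snippet(text, m, window=window, snippet_id=f"{note_id}:{i}")
        for i, m in enumerate(find_term_matches(text, lexicon, note_id=note_id))
    ]
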