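"""Tokenization, taxonomy matching and snippet extraction."""

import re

import pytest
from hypothesis import given, settings, strategies as st

import fsnlp
from fsnlp.lexicon import Lexicon, TermMatch, extract_snippet, find_term_matches, tokenize


def brute_force_matches(text, lexicon):
    """Oracle: enumerate every phrase occurrence by scanning token windows,
    then resolve overlaps longest-first / leftmost-first independently of the
    implementation's search order."""
    tk = tokenize(text)
    occurrences = []
    for i in range(len(tk.tokens)):
        for term in lexicon:
            if tuple(tk.tokens[i : i + len(term)]) == term:
                occurrences.append((i, i + len(term), term))
    chosen = []
    for start, end, term in sorted(occurrences, key=lambda o: (-(o[1] - o[0]), o[0])):
        if all(end <= s or start >= e for s, e, _ in chosen):
            chosen.append((start, end, term))
    return sorted(chosen)


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("patient owns a shotgun", ["patient", "owns", "a", "shotgun"]),
            ("", []),
            ("9 mm Glock!", ["9", "mm", "glock"]),
            ("9-mm", ["9", "mm"]),
            ("9mm Glock", ["9", "mm", "glock"]),  # digit+unit fusion split
            ("12gauge", ["12", "gauge"]),
            ("M1 rifle", ["m1", "rifle"]),  # generic digit/letter mix kept whole
        ],
    )
    def test_examples(self, text, expected):
        assert list(tokenize(text).tokens) == expected

    def test_spans_map_back_to_source(self):
        text = "Veteran OWNS a 12-gauge; stored (unloaded)."
        tk = tokenize(text)
        for tok, (a, b) in zip(tk.tokens, tk.spans):
            assert text[a:b].lower() == tok

    @given(st.text(max_size=200))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_token_charset_and_span_order(self, text):
        tk = tokenize(text)
        assert len(tk.tokens) == len(tk.spans)
        prev_end = -1
        for tok, (a, b) in zip(tk.tokens, tk.spans):
            assert re.fullmatch(r"[a-z0-9]+", tok)
            assert a >= prev_end and a < b
            prev_end = b


class TestLexicon:
    def test_default_has_27_unique_phrases(self, lexicon):
        assert len(lexicon) == 27
        assert len(set(lexicon.terms)) == 27

    def test_rejects_duplicates_and_empty_phrases(self):
        with pytest.raises(ValueError):
            Lexicon.from_phrases(["rifle", "Rifle"])
        with pytest.raises(ValueError):
            Lexicon(terms=((),))

    def test_from_file_roundtrip(self, tmp_path, lexicon):
        p = tmp_path / "terms.txt"
        p.write_text("# comment\nrifle\nsniper rifle\n\n")
        lex = Lexicon.from_file(p)
        assert lex.terms == (("rifle",), ("sniper", "rifle"))


class TestMatching:
    def test_single_term(self, lexicon):
        (m,) = find_term_matches("patient owns a shotgun", lexicon)
        assert m.term == ("shotgun",) and m.token_start == 3

    def test_no_term(self, lexicon):
        assert find_term_matches("no relevant content here", lexicon) == []

    def test_longest_match_suppresses_inner_term(self, lexicon):
        (m,) = find_term_matches("he cleaned his sniper rifle", lexicon)
        assert m.term == ("sniper", "rifle")

    def test_case_and_punctuation_invariance(self, lexicon):
        variants = [
            "keeps a shotgun at home",
            "keeps a SHOTGUN at home",
            "keeps a (shotgun!) at home",
        ]
        results = [
            [(m.term, m.token_start) for m in find_term_matches(v, lexicon)] for v in variants
        ]
        assert results[0] == results[1] == results[2] == [(("shotgun",), 2)]

    def test_matches_are_token_bounded(self, lexicon):
        # "shotgunner" must not match "shotgun"; tokens are maximal runs.
        assert find_term_matches("the shotgunner arrived", lexicon) == []

    def test_matches_never_overlap_and_agree_with_brute_force(self, lexicon):
        texts = [
            "sniper rifle and rifle and winchester rifle together",
            "a gun guns firearm firearms pistol whip pistol",
            "mossberg shotgun shotgun 12 gauge 9 mm glock 9mm glock",
            "ruger pistol whip smith and wesson revolver",
        ]
        for text in texts:
            got = [(m.token_start, m.token_end, m.term) for m in find_term_matches(text, lexicon)]
            assert got == brute_force_matches(text, lexicon)
            for (s1, e1, _), (s2, e2, _) in zip(got, got[1:]):
                assert e1 <= s2

    def test_match_records_consistent_char_span(self, lexicon):
        text = "Veteran keeps his Winchester Rifle cleaned."
        (m,) = find_term_matches(text, lexicon)
        assert text[m.char_span[0] : m.char_span[1]].lower() == "winchester rifle"


class TestCounting:
    def test_direct_counts_and_zero_terms(self, lexicon):
        corpus = [{"note_id": f"n{i}", "text": "a rifle here"} for i in range(3)]
        counts, skipped = fsnlp.count_term_frequencies(corpus, lexicon)
        assert skipped == 0
        assert counts["rifle"] == 3
        assert counts["pistol"] == 0
        assert set(counts) == {" ".join(t) for t in lexicon.terms}

    def test_empty_corpus_all_zero(self, lexicon):
        counts, _ = fsnlp.count_term_frequencies([], lexicon)
        assert all(v == 0 for v in counts.values())

    def test_unreadable_record_skipped(self, lexicon):
        corpus = [{"note_id": "n1", "text": "a rifle"}, {"note_id": "n2"}]
        counts, skipped = fsnlp.count_term_frequencies(corpus, lexicon)
        assert skipped == 1 and counts["rifle"] == 1

    def test_counts_conserve_per_note_matches(self, lexicon):
        records, _ = fsnlp.generate_corpus(200, seed=1)
        counts, _ = fsnlp.count_term_frequencies(records, lexicon)
        expected = {" ".join(t): 0 for t in lexicon.terms}
        for rec in records:
            for m in find_term_matches(rec["text"], lexicon):
                expected[m.term_text] += 1
        assert counts == expected


class TestSnippets:
    def _note(self, n_tokens, term_at, term="sniper rifle"):
        words = [f"w{i}" for i in range(n_tokens)]
        words[term_at : term_at + len(term.split())] = term.split()
        return " ".join(words)

    def test_interior_window(self, lexicon):
        text = self._note(300, 100)
        (m,) = find_term_matches(text, lexicon)
        s = extract_snippet(text, m, window=35)
        assert len(s.tokens) == 72 and s.keyphrase_offset == 35
        assert s.keyphrase == ("sniper", "rifle")

    def test_boundary_truncation(self, lexicon):
        text = self._note(300, 10)
        (m,) = find_term_matches(text, lexicon)
        s = extract_snippet(text, m, window=35)
        assert s.keyphrase_offset == 10
        assert s.tokens[0] == "w0"

    def test_default_window_is_35(self):
        assert fsnlp.DEFAULT_WINDOW == 35

    def test_stale_match_rejected(self, lexicon):
        text = self._note(50, 10)
        (m,) = find_term_matches(text, lexicon)
        with pytest.raises(ValueError, match="stale"):
            extract_snippet("completely different text", m)

    def test_roundtrip_on_synthetic_corpus(self, lexicon):
        """Every match's snippet contains the term at the recorded offset."""
        records, _ = fsnlp.generate_corpus(1000, seed=2)
        n_checked = 0
        for rec in records:
            for m in find_term_matches(rec["text"], lexicon, note_id=rec["note_id"]):
                s = extract_snippet(rec["text"], m)
                assert s.keyphrase == m.term
                assert len(s.tokens) <= 2 * s.window + s.keyphrase_len
                n_checked += 1
        assert n_checked > 500
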