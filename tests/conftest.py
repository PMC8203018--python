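import dataclasses

import numpy as np
import pytest

import fsnlp


@pytest.fixture(scope="session")
def lexicon():
    return fsnlp.Lexicon.default()


@pytest.fixture(scope="session")
def corpus2000():
    """The default synthetic corpus exercised by the end-to-end properties."""
    records, gold = fsnlp.generate_corpus(n=2000, seed=11)
    return records, gold


@pytest.fixture(scope="session")
def trained(corpus2000, lexicon):
    """Snippets, split, vocabulary and fitted forest for the 2000-note corpus.

    Returns a dict with everything downstream checks need so the expensive
    training happens once per session.
    """
    records, gold = corpus2000
    gold_map = dict(zip(gold["note_id"], gold["gold_label"]))
    snippets, labels = [], []
    snippets_by_note = {}
    for rec in records:
        snips = fsnlp.extract_all_snippets(rec["text"], lexicon, note_id=rec["note_id"])
        snippets_by_note[rec["note_id"]] = snips
        if gold_map[rec["note_id"]] == "distractor":
            continue
        for s in snips:
            snippets.append(s)
            labels.append(fsnlp.AccessLabel(gold_map[rec["note_id"]]))
    train_idx, test_idx = fsnlp.split_train_test(
        snippets, [l.value for l in labels], train_fraction=0.85, seed=11
    )
    train_snips = [snippets[i] for i in train_idx]
    vocab = fsnlp.build_vocabulary(train_snips)
    clf = fsnlp.train_classifier(
        train_snips,
        [labels[i] for i in train_idx],
        vocab,
        fsnlp.ClassifierConfig(seed=11),
    )
    return {
        "records": records,
        "gold_map": gold_map,
        "snippets": snippets,
        "labels": labels,
        "snippets_by_note": snippets_by_note,
        "train_idx": train_idx,
        "test_idx": test_idx,
        "vocab": vocab,
        "clf": clf,
    }


@pytest.fixture(scope="session")
def cohort50k():
    """Default synthetic cohort at n=50,000 (no events) for model recovery."""
    spec = dataclasses.replace(fsnlp.CohortGeneratorSpec(), n=50_000, seed=3)
    cohort, _ = fsnlp.generate_cohort(spec, with_events=False)
    return spec, cohort
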