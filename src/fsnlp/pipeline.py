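"""End-to-end orchestration: match -> snippets -> train -> classify -> eval.

`run_pipeline` executes the stages on note corpora with gold snippet labels
(real annotation files or synthetic gold), writes each stage's output before
the next starts, and returns a JSON-serializable run manifest with record
counts, metrics, the config hash and package versions, so a run is fully
reproducible from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .annotation import AccessLabel, collapse_binary
from .features import build_vocabulary, split_train_test
from .io import read_notes, write_jsonl
from .lexicon import DEFAULT_WINDOW, Lexicon, extract_all_snippets, find_term_matches
from .metrics import ConfusionMatrix, compute_metrics
from .model import ClassifierConfig, NoteLabel, aggregate_snippet_labels, train_classifier

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    notes_path: str
    gold_path: str  # CSV: note_id, gold_label (positive/negative/ambiguous/distractor)
    out_dir: str
    lexicon_path: str | None = None
    window: int = DEFAULT_WINDOW
    min_unigram: int = 35
    min_bigram: int = 5
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    split_seed: int | None = None

    def validate(self) -> None:
        for name in ("notes_path", "gold_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if self.lexicon_path is not None and not Path(self.lexicon_path).exists():
            raise FileNotFoundError(f"lexicon_path does not exist: {self.lexicon_path}")
        if self.split_seed is None:
            raise ValueError("split_seed must be set explicitly (every random stage is seeded)")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        clf = raw.pop("classifier", {})
        return cls(classifier=ClassifierConfig(**clf), **raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the run manifest.

    Stages: load notes -> term matching -> snippet extraction -> vocabulary
    and training on the train split -> snippet evaluation on the test split
    -> note-level classification of the whole corpus -> note-level binary
    evaluation against gold (AMBIGUOUS collapsing to the negative side).
    Any stage failure aborts with the stage name and records processed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.digest(),
        "fsnlp_version": __version__,
        "stages": {},
    }
    lexicon = Lexicon.from_file(config.lexicon_path) if config.lexicon_path else Lexicon.default()

    stage = "load_notes"
    try:
        notes = read_notes(config.notes_path)
        gold = pd.read_csv(config.gold_path, dtype=str).set_index("note_id")["gold_label"]
        manifest["stages"][stage] = {"notes_in": len(notes)}

        stage = "match"
        matches_out = []
        snippets_by_note: dict[str, list] = {}
        for rec in notes:
            snips = extract_all_snippets(
                rec["text"], lexicon, note_id=rec["note_id"], window=config.window
            )
            snippets_by_note[rec["note_id"]] = snips
            for s in snips:
                matches_out.append(
                    {
                        "snippet_id": s.snippet_id,
                        "note_id": s.note_id,
                        "keyphrase": " ".join(s.keyphrase),
                        "keyphrase_offset": s.keyphrase_offset,
                        "tokens": " ".join(s.tokens),
                    }
                )
        write_jsonl(matches_out, out_dir / "snippets.jsonl")
        manifest["stages"][stage] = {
            "notes_in": len(notes),
            "notes_with_match": sum(bool(v) for v in snippets_by_note.values()),
            "snippets_out": len(matches_out),
        }

        stage = "train"
        labelled = [
            (s, AccessLabel(gold[nid]))
            for nid, snips in snippets_by_note.items()
            if gold.get(nid) in {"positive", "negative", "ambiguous"}
            for s in snips
        ]
        if not labelled:
            raise ValueError("no labelled snippets available for training")
        snips = [s for s, _ in labelled]
        labels = [l for _, l in labelled]
        seed = config.split_seed
        train_idx, test_idx = split_train_test(
            snips, [l.value for l in labels], config.classifier.train_fraction, seed=seed
        )
        train_snips = [snips[i] for i in train_idx]
        vocab_snips = train_snips if config.classifier.vocab_scope == "train" else snips
        vocab = build_vocabulary(vocab_snips, config.min_unigram, config.min_bigram)
        clf = train_classifier(train_snips, [labels[i] for i in train_idx], vocab, config.classifier)
        manifest["stages"][stage] = {
            "snippets_train": len(train_idx),
            "snippets_test": len(test_idx),
            "vocab_unigrams": len(vocab.unigrams),
            "vocab_bigrams": len(vocab.bigrams),
        }

        stage = "eval_snippets"
        test_pred = clf.predict_many([snips[i] for i in test_idx])
        test_true = [labels[i] for i in test_idx]
        if config.classifier.label_scheme == "binary":
            test_true = [collapse_binary(l) for l in test_true]
        acc = (
            sum(p is t for p, t in zip(test_pred, test_true)) / len(test_idx)
            if test_idx
            else float("nan")
        )
        manifest["stages"][stage] = {"n_test": len(test_idx), "holdout_accuracy": acc}

        stage = "classify_notes"
        rows = []
        for rec in notes:
            label = aggregate_snippet_labels(clf.predict_many(snippets_by_note[rec["note_id"]]))
            rows.append({"note_id": rec["note_id"], "label": label.value})
        pred_df = pd.DataFrame(rows)
        pred_df.to_csv(out_dir / "note_labels.csv", index=False)
        manifest["stages"][stage] = {"notes_in": len(notes), "notes_classified": len(rows)}

        stage = "eval_notes"
        merged = pred_df.merge(gold.reset_index(), on="note_id")
        truth = (merged["gold_label"] == "positive").tolist()
        pred = (merged["label"] == NoteLabel.POSITIVE.value).tolist()
        cm = ConfusionMatrix.from_labels(truth, pred)
        m = compute_metrics(cm)
        manifest["stages"][stage] = {
            "n": cm.total,
            "tp": cm.tp,
            "fp": cm.fp,
            "tn": cm.tn,
            "fn": cm.fn,
            "accuracy": m.accuracy,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "ppv": m.ppv,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
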