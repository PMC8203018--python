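"""Readers and writers for note corpora, labels and tables.

Notes travel as JSONL (one object per line: note_id, patient_id, date,
clinic, text) or as an equivalent CSV; labels and tables as CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

NOTE_FIELDS = ("note_id", "patient_id", "date", "clinic", "text")
VALID_CLINICS = {"primary", "urgent", "emergency", "mental_health", "other"}


def read_notes(path: str | Path) -> list[dict]:
    """Load note records from a .jsonl or .csv file."""
    path = Path(path)
    if path.suffix.lower() == ".jsonl":
        records = list(iter_jsonl(path))
    elif path.suffix.lower() == ".csv":
        records = pd.read_csv(path, dtype=str).to_dict("records")
    else:
        raise ValueError(f"unsupported notes format: {path.suffix!r} (use .jsonl or .csv)")
    for rec in records:
        missing = [f for f in NOTE_FIELDS if f not in rec or pd.isna(rec[f])]
        if missing:
            raise ValueError(f"note record missing fields {missing}: {rec.get('note_id', '?')}")
    return records


def iter_jsonl(path: str | Path) -> Iterator[dict]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield json.loads(line)


def write_jsonl(records: Iterable[dict], path: str | Path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
            n += 1
    return n


def write_notes(records: Iterable[dict], path: str | Path) -> int:
    path = Path(path)
    if path.suffix.lower() == ".jsonl":
        return write_jsonl(records, path)
    if path.suffix.lower() == ".csv":
        df = pd.DataFrame(list(records))
        df.to_csv(path, index=False)
        return len(df)
    raise ValueError(f"unsupported notes format: {path.suffix!r}")
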