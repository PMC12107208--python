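"""Reading and writing the pipeline's text formats.

Corpora travel as JSON Lines (one record object per line: record_id,
model_label, disease, prompt_id, text); ground truth and all report tables
as delimited text with a header row, UTF-8, newline-terminated.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .corpus import EHRRecord, GroundTruth
from .errors import ValidationError

log = logging.getLogger("ehraudit")

_FIELDS = ("record_id", "model_label", "disease", "prompt_id", "text")


def write_corpus(records: list[EHRRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps({f: getattr(r, f) for f in _FIELDS}) + "\n")


def read_corpus(
    path: str | Path, max_malformed_fraction: float = 0.01
) -> list[EHRRecord]:
    """Parse a JSONL corpus; malformed lines are skipped and counted, and the
    read fails when they exceed ``max_malformed_fraction`` of all lines."""
    path = Path(path)
    records: list[EHRRecord] = []
    n_bad = n_lines = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            n_lines += 1
            try:
                obj = json.loads(line)
                records.append(
                    EHRRecord(
                        record_id=str(obj["record_id"]),
                        model_label=str(obj["model_label"]),
                        disease=str(obj["disease"]),
                        prompt_id=int(obj["prompt_id"]),
                        text=str(obj["text"]),
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                n_bad += 1
    if n_bad:
        log.warning("skipped %d malformed corpus line(s) in %s", n_bad, path)
    if n_lines == 0:
        raise ValidationError(f"empty corpus file {path}")
    if n_bad / n_lines > max_malformed_fraction:
        raise ValidationError(
            f"{n_bad}/{n_lines} malformed lines in {path} exceeds the "
            f"{max_malformed_fraction:.0%} tolerance"
        )
    return records


def write_ground_truth(truths: list[GroundTruth], path: str | Path, sep: str = ",") -> None:
    attrs = sorted({a for t in truths for a in t.categories})
    rows = [
        {"record_id": t.record_id, "completeness_class": t.completeness_class,
         **{a: t.categories.get(a, "") for a in attrs}}
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_table(df: pd.DataFrame, path: str | Path, fmt: str = "csv") -> None:
    """Write a report table as csv, tsv or json (records orientation)."""
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(df.to_json(orient="records", indent=2) + "\n", encoding="utf-8")
    else:
        raise ValidationError(f"unknown output format {fmt!r}")
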