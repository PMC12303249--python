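"""Readers and writers for the pipeline's plain-text artifact formats.

JSONL for note/snippet/document streams, CSV for tabular outputs
(labels/reviews, triage, predictions), JSON for metric reports and run
manifests.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

from .classify import PredictionRecord
from .corpus import ReviewRecord, SyntheticCohort
from .errors import ConfigurationError
from .labels import AccessLabel, BinaryLabel
from .snippets import Note, PatientDocument, Snippet
from .triage import Reason, Route, TriageDecision


def write_jsonl(path, rows: Iterable[Mapping]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for row in rows:
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")


def read_jsonl(path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


# -- corpus -----------------------------------------------------------------

def write_corpus(path, notes: Iterable[Note]) -> None:
    write_jsonl(
        path,
        (
            {
                "patient_id": n.patient_id,
                "note_id": n.note_id,
                "note_date": n.note_date,
                "specialty": n.specialty,
                "text": n.text,
            }
            for n in notes
        ),
    )


def read_corpus(path) -> list[Note]:
    notes = []
    for row in read_jsonl(path):
        try:
            notes.append(
                Note(
                    patient_id=row["patient_id"],
                    note_id=row["note_id"],
                    note_date=row.get("note_date", ""),
                    specialty=row.get("specialty", ""),
                    text=row["text"],
                )
            )
        except KeyError as exc:
            raise ConfigurationError(f"corpus row missing field {exc}") from None
    return notes


# -- labels / reviews -------------------------------------------------------

LABELS_HEADER = ["patient_id", "truth_label", "reviewer1", "reviewer2", "consensus", "disagreement"]


def write_labels(path, cohort: SyntheticCohort) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LABELS_HEADER)
        for p in cohort.patients:
            r = p.review
            writer.writerow(
                [
                    p.patient_id,
                    p.truth.value,
                    r.reviewer_labels[0].value,
                    r.reviewer_labels[1].value,
                    r.consensus.value,
                    int(r.had_disagreement),
                ]
            )


def read_labels(path) -> tuple[dict[str, AccessLabel], list[ReviewRecord]]:
    truth: dict[str, AccessLabel] = {}
    reviews: list[ReviewRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row["patient_id"]
            truth[pid] = AccessLabel.parse(row["truth_label"])
            reviews.append(
                ReviewRecord(
                    patient_id=pid,
                    reviewer_labels=(
                        AccessLabel.parse(row["reviewer1"]),
                        AccessLabel.parse(row["reviewer2"]),
                    ),
                    consensus=AccessLabel.parse(row["consensus"]),
                    had_disagreement=bool(int(row["disagreement"])),
                )
            )
    return truth, reviews


# -- snippets / documents ---------------------------------------------------

def write_snippets(path, snippets: Iterable[Snippet]) -> None:
    write_jsonl(
        path,
        (
            {
                "patient_id": s.patient_id,
                "note_id": s.note_id,
                "keyword": s.keyword,
                "start_word": s.start_word,
                "end_word": s.end_word,
                "text": s.text,
            }
            for s in snippets
        ),
    )


def write_documents(path, documents: Iterable[PatientDocument]) -> None:
    write_jsonl(
        path,
        (
            {
                "patient_id": d.patient_id,
                "text": d.text,
                "snippet_count": d.snippet_count,
                "word_count": d.word_count,
            }
            for d in documents
        ),
    )


def read_documents(path) -> list[PatientDocument]:
    return [
        PatientDocument(
            patient_id=row["patient_id"],
            text=row["text"],
            snippet_count=row["snippet_count"],
            word_count=row["word_count"],
        )
        for row in read_jsonl(path)
    ]


# -- triage -----------------------------------------------------------------

TRIAGE_HEADER = ["patient_id", "route", "reason", "snippet_count", "word_count"]


def write_triage(path, rows: Iterable[tuple[PatientDocument, TriageDecision]]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAGE_HEADER)
        for doc, decision in rows:
            writer.writerow(
                [doc.patient_id, decision.route.value, decision.reason.value, doc.snippet_count, doc.word_count]
            )


def read_triage(path) -> dict[str, TriageDecision]:
    decisions: dict[str, TriageDecision] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            decisions[row["patient_id"]] = TriageDecision(
                route=Route(row["route"]), reason=Reason(row["reason"])
            )
    return decisions


# -- predictions ------------------------------------------------------------

PREDICTIONS_HEADER = ["patient_id", "route", "category", "binary", "parse_ok"]


def write_predictions(path, records: Iterable[PredictionRecord]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PREDICTIONS_HEADER)
        for r in records:
            writer.writerow(
                [r.patient_id, r.route.value, r.category.value, r.binary.value, int(r.parse_ok)]
            )


def read_predictions(path) -> list[PredictionRecord]:
    records = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                PredictionRecord(
                    patient_id=row["patient_id"],
                    route=Route(row["route"]),
                    raw_response="",
                    category=AccessLabel.parse(row["category"]),
                    binary=BinaryLabel(row["binary"]),
                    parse_ok=bool(int(row["parse_ok"])),
                )
            )
    return records


# -- reports / manifests ----------------------------------------------------

def write_json(path, payload: Mapping) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_hash(payload: Mapping) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]
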