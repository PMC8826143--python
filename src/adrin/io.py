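"""Reading and writing the pipeline's text formats.

Notes travel as JSONL (canonical: free text with commas and newlines
survives) or CSV with the same columns; medication-stop registrations as
CSV; gold annotations as JSONL; embedding tables in the word2vec text
format.  All readers raise :class:`FormatError` with the offending
column or row when a file does not match its contract.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional

from .embedding import VectorStore

__all__ = [
    "FormatError",
    "RawNote",
    "MedicationRecord",
    "GoldAnnotation",
    "read_notes",
    "write_notes",
    "read_medication_records",
    "read_gold",
    "write_gold",
    "join_stops_to_notes",
    "read_vector_store",
    "write_vector_store",
]


class FormatError(ValueError):
    """A file does not match the expected format."""


@dataclass(frozen=True)
class RawNote:
    """One free-text clinical note as written in the health record."""

    note_id: str
    patient_id: str
    date: date
    text: str

    @property
    def is_empty(self) -> bool:
        return not self.text.strip()


@dataclass(frozen=True)
class MedicationRecord:
    """A prescription registration; discontinued iff a stop date exists."""

    patient_id: str
    drug: str
    start_date: date
    stop_date: Optional[date] = None
    stop_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.stop_date is not None and self.stop_date < self.start_date:
            raise ValueError(
                f"stop_date {self.stop_date} precedes start_date "
                f"{self.start_date} for {self.drug!r}"
            )

    @property
    def discontinued(self) -> bool:
        return self.stop_date is not None


@dataclass(frozen=True)
class GoldAnnotation:
    """Manual labels for one note: ADR presence, mentions and pairs."""

    note_id: str
    has_adr: bool
    medications: tuple[str, ...] = ()
    adrs: tuple[str, ...] = ()
    pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "medications", tuple(self.medications))
        object.__setattr__(self, "adrs", tuple(self.adrs))
        object.__setattr__(
            self, "pairs", tuple((m, a) for m, a in self.pairs)
        )
        if self.has_adr != (bool(self.pairs) or bool(self.adrs)):
            raise ValueError(
                f"note {self.note_id}: has_adr must reflect the presence "
                "of annotated ADRs"
            )
        for med, adr in self.pairs:
            if med not in self.medications or adr not in self.adrs:
                raise ValueError(
                    f"note {self.note_id}: pair ({med!r}, {adr!r}) not "
                    "covered by the mention lists"
                )


_NOTE_FIELDS = ("note_id", "patient_id", "date", "text")


def _parse_date(value: str, where: str) -> date:
    try:
        return date.fromisoformat(value)
    except ValueError as exc:
        raise FormatError(f"{where}: invalid date {value!r}") from exc


def read_notes(path, format: Optional[str] = None) -> list[RawNote]:
    """Read notes from JSONL or CSV (inferred from the suffix).

    Empty-text notes are retained; the pipeline runner decides what to
    do with them.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unknown notes format {format!r}")

    notes: list[RawNote] = []
    seen: set[str] = set()
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            missing = [
                c for c in _NOTE_FIELDS if c not in (reader.fieldnames or [])
            ]
            if missing:
                raise FormatError(
                    f"{path}: missing column(s): {', '.join(missing)}"
                )
            for i, row in enumerate(reader):
                where = f"{path}: row {i + 1}"
                if any(row.get(c) is None for c in _NOTE_FIELDS):
                    raise FormatError(f"{where}: short row")
                notes.append(
                    RawNote(
                        note_id=row["note_id"],
                        patient_id=row["patient_id"],
                        date=_parse_date(row["date"], where),
                        text=row["text"],
                    )
                )
    else:
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                if not line.strip():
                    continue
                where = f"{path}: line {i + 1}"
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise FormatError(f"{where}: invalid JSON") from exc
                missing = [c for c in _NOTE_FIELDS if c not in obj]
                if missing:
                    raise FormatError(
                        f"{where}: missing key(s): {', '.join(missing)}"
                    )
                notes.append(
                    RawNote(
                        note_id=str(obj["note_id"]),
                        patient_id=str(obj["patient_id"]),
                        date=_parse_date(obj["date"], where),
                        text=str(obj["text"]),
                    )
                )
    for n in notes:
        if n.note_id in seen:
            raise FormatError(f"{path}: duplicate note_id {n.note_id!r}")
        seen.add(n.note_id)
    return notes


def write_notes(notes: Iterable[RawNote], path, format: Optional[str] = None
                ) -> None:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_NOTE_FIELDS)
            writer.writeheader()
            for n in notes:
                writer.writerow(
                    {
                        "note_id": n.note_id,
                        "patient_id": n.patient_id,
                        "date": n.date.isoformat(),
                        "text": n.text,
                    }
                )
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for n in notes:
                fh.write(
                    json.dumps(
                        {
                            "note_id": n.note_id,
                            "patient_id": n.patient_id,
                            "date": n.date.isoformat(),
                            "text": n.text,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )


def read_medication_records(path) -> list[MedicationRecord]:
    """Read medication registrations from CSV.

    Columns: patient_id, drug, start_date, stop_date (may be empty),
    stop_reason (may be empty).
    """
    required = ("patient_id", "drug", "start_date")
    records: list[MedicationRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(
                f"{path}: missing column(s): {', '.join(missing)}"
            )
        for i, row in enumerate(reader):
            where = f"{path}: row {i + 1}"
            stop_raw = (row.get("stop_date") or "").strip()
            records.append(
                MedicationRecord(
                    patient_id=row["patient_id"],
                    drug=row["drug"],
                    start_date=_parse_date(row["start_date"], where),
                    stop_date=(
                        _parse_date(stop_raw, where) if stop_raw else None
                    ),
                    stop_reason=(row.get("stop_reason") or None),
                )
            )
    return records


def read_gold(path) -> list[GoldAnnotation]:
    """Read gold annotations from JSONL."""
    gold: list[GoldAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            where = f"{path}: line {i + 1}"
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{where}: invalid JSON") from exc
            try:
                gold.append(
                    GoldAnnotation(
                        note_id=str(obj["note_id"]),
                        has_adr=bool(obj["has_adr"]),
                        medications=tuple(obj.get("medications", ())),
                        adrs=tuple(obj.get("adrs", ())),
                        pairs=tuple(
                            (m, a) for m, a in obj.get("pairs", ())
                        ),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{where}: {exc}") from exc
    return gold


def write_gold(gold: Iterable[GoldAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in gold:
            fh.write(
                json.dumps(
                    {
                        "note_id": g.note_id,
                        "has_adr": g.has_adr,
                        "medications": list(g.medications),
                        "adrs": list(g.adrs),
                        "pairs": [list(p) for p in g.pairs],
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def join_stops_to_notes(
    records: Iterable[MedicationRecord], notes: Iterable[RawNote]
) -> list[tuple[MedicationRecord, RawNote]]:
    """Pair each discontinued record with every same-patient note written
    on the stop date.

    When several prescriptions of one patient stop on the same day, the
    same note is reused for all of them; records without a matching note
    (or without a stop date) are silently omitted.
    """
    by_key: dict[tuple[str, date], list[RawNote]] = {}
    for n in notes:
        by_key.setdefault((n.patient_id, n.date), []).append(n)
    pairs: list[tuple[MedicationRecord, RawNote]] = []
    for rec in records:
        if rec.stop_date is None:
            continue
        for note in by_key.get((rec.patient_id, rec.stop_date), []):
            pairs.append((rec, note))
    return pairs


def read_vector_store(path) -> VectorStore:
    """Read an embedding table in word2vec text format."""
    try:
        return VectorStore.load(path)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_vector_store(store: VectorStore, path) -> None:
    store.save(path)
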