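"""Corpus data model and file I/O.

The unit of classification is the hospital *encounter* (one admission).
Each encounter links free-text notes of four types (emergency,
history-of-present-illness, discharge, other), the top-5 discharge
diagnosis codes for the visit, and all ICD-10 codes on the patient's
chart history.  Gold-standard labels come from manual chart review.

Formats: notes are JSONL (one record per line: note_id, encounter_id,
note_type, text); codes and labels are CSV.  ICD-10 codes are
canonicalized to uppercase with the dot removed, so "F11.20" and "F1120"
compare equal, and code-list membership is prefix-based ("F11" matches
"F11.20") because published substance-use code lists are typically
category-level.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger("pwudflag")

NOTE_TYPES = ("emergency", "hpi", "discharge", "other")
REVIEWED_NOTE_TYPES = ("emergency", "hpi", "discharge")

PWUD = "pwud"
NOT_PWUD = "not_pwud"


@dataclass(frozen=True)
class Note:
    note_id: str
    encounter_id: str
    note_type: str
    text: str

    def __post_init__(self) -> None:
        if self.note_type not in NOTE_TYPES:
            raise ValueError(f"note {self.note_id!r}: bad note_type {self.note_type!r}")


@dataclass
class Encounter:
    encounter_id: str
    patient_id: str = ""
    visit_codes: list[str] = field(default_factory=list)
    history_codes: list[str] = field(default_factory=list)
    notes: list[Note] = field(default_factory=list)

    def __post_init__(self) -> None:
        for n in self.notes:
            if n.encounter_id != self.encounter_id:
                raise ValueError(
                    f"note {n.note_id!r} belongs to {n.encounter_id!r}, "
                    f"not {self.encounter_id!r}"
                )
        self.visit_codes = [canonicalize_code(c) for c in self.visit_codes]
        self.history_codes = [canonicalize_code(c) for c in self.history_codes]


@dataclass
class GoldLabel:
    encounter_id: str
    label: str
    per_chart_labels: dict[str, bool] | None = None
    reviewer_labels: tuple[bool, bool] | None = None
    tiebreaker: bool | None = None

    def __post_init__(self) -> None:
        if self.label not in (PWUD, NOT_PWUD):
            raise ValueError(f"bad label {self.label!r}")
        if self.per_chart_labels is not None:
            extra = set(self.per_chart_labels) - set(REVIEWED_NOTE_TYPES)
            if extra:
                raise ValueError(f"per-chart labels for unreviewed types: {sorted(extra)}")

    @property
    def is_positive(self) -> bool:
        return self.label == PWUD


def canonicalize_code(code: str) -> str:
    """Canonical ICD-10 form: uppercase, dot stripped. Idempotent."""
    c = code.strip().upper().replace(".", "")
    if not c:
        raise ValueError("empty ICD-10 code")
    return c


def code_matches(code: str, code_list: set[str] | frozenset[str]) -> bool:
    """True when the canonicalized code starts with any canonical prefix in code_list."""
    canon = canonicalize_code(code)
    return any(canon.startswith(canonicalize_code(p)) for p in code_list)


def read_notes(path) -> list[Note]:
    """Read notes from JSONL; unknown note types map to 'other' with a warning."""
    notes: list[Note] = []
    seen: set[str] = set()
    n_coerced = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                note_id = rec["note_id"]
                encounter_id = rec["encounter_id"]
                note_type = rec["note_type"]
                text = rec["text"]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: malformed note record at line {lineno}: {exc}")
            if note_id in seen:
                raise ValueError(f"{path}: duplicate note_id {note_id!r} at line {lineno}")
            seen.add(note_id)
            if note_type not in NOTE_TYPES:
                logger.warning(
                    "note %s: unknown note_type %r mapped to 'other'", note_id, note_type
                )
                note_type = "other"
                n_coerced += 1
            notes.append(Note(str(note_id), str(encounter_id), note_type, str(text)))
    if n_coerced:
        logger.warning("%d notes had unknown note_type coerced to 'other'", n_coerced)
    return notes


def write_notes(notes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": n.note_id,
                        "encounter_id": n.encounter_id,
                        "note_type": n.note_type,
                        "text": n.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_codes(path) -> dict[str, tuple[list[str], list[str]]]:
    """Read the codes CSV (encounter_id, code, scope in {visit, history}).

    Returns encounter_id -> (visit_codes, history_codes), canonicalized.
    """
    out: dict[str, tuple[list[str], list[str]]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"encounter_id", "code", "scope"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: codes CSV must have columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            scope = row["scope"].strip().lower()
            if scope not in ("visit", "history"):
                raise ValueError(f"{path} line {lineno}: unknown scope {row['scope']!r}")
            code = canonicalize_code(row["code"])  # raises on empty
            visit, history = out.setdefault(row["encounter_id"], ([], []))
            (visit if scope == "visit" else history).append(code)
    return out


def write_codes(codes: dict[str, tuple[list[str], list[str]]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["encounter_id", "code", "scope"])
        for eid in codes:
            visit, history = codes[eid]
            for c in visit:
                w.writerow([eid, c, "visit"])
            for c in history:
                w.writerow([eid, c, "history"])


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in ("1", "true", "t", "yes"):
        return True
    if v in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def read_labels(path) -> dict[str, GoldLabel]:
    """Read gold labels CSV: encounter_id, label, optional per-chart boolean columns."""
    out: dict[str, GoldLabel] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "encounter_id" not in reader.fieldnames:
            raise ValueError(f"{path}: labels CSV needs an encounter_id column")
        chart_cols = [c for c in REVIEWED_NOTE_TYPES if c in (reader.fieldnames or [])]
        for lineno, row in enumerate(reader, start=2):
            eid = row["encounter_id"]
            if eid in out:
                raise ValueError(f"{path} line {lineno}: duplicate label for {eid!r}")
            per_chart = None
            if chart_cols:
                per_chart = {c: _parse_bool(row[c]) for c in chart_cols if row[c] != ""}
                per_chart = per_chart or None
            out[eid] = GoldLabel(eid, row["label"].strip().lower(), per_chart)
    return out


def write_labels(labels: dict[str, GoldLabel], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["encounter_id", "label"])
        for eid, lab in labels.items():
            w.writerow([eid, lab.label])


def assemble_corpus(
    notes,
    codes: dict[str, tuple[list[str], list[str]]],
    labels: dict[str, GoldLabel] | None = None,
    patient_ids: dict[str, str] | None = None,
) -> list[Encounter]:
    """Group notes and codes into Encounters.

    Encounter ids are the union of those seen in notes and codes; encounters
    without codes get empty code lists (warned).  When labels are supplied,
    every label must refer to a known encounter and every encounter must be
    labeled, otherwise the offending ids are reported.
    """
    by_encounter: dict[str, list] = {}
    for n in notes:
        by_encounter.setdefault(n.encounter_id, []).append(n)
    all_ids = list(dict.fromkeys(list(by_encounter) + list(codes)))

    missing_codes = [eid for eid in all_ids if eid not in codes]
    if missing_codes:
        logger.warning(
            "%d encounters have no ICD-10 codes (e.g. %s); using empty code lists",
            len(missing_codes),
            missing_codes[:3],
        )
    if labels is not None:
        known = set(all_ids)
        unknown = sorted(set(labels) - known)
        if unknown:
            raise ValueError(f"labels refer to unknown encounters: {unknown}")
        unlabeled = sorted(known - set(labels))
        if unlabeled:
            raise ValueError(f"encounters without gold labels: {unlabeled}")

    encounters = []
    for eid in all_ids:
        visit, history = codes.get(eid, ([], []))
        encounters.append(
            Encounter(
                encounter_id=eid,
                patient_id=(patient_ids or {}).get(eid, ""),
                visit_codes=list(visit),
                history_codes=list(history),
                notes=by_encounter.get(eid, []),
            )
        )
    return encounters
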