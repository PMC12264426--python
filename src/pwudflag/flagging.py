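"""Encounter-level aggregation: note-fraction thresholds and ICD-10 flags.

A note-level flag becomes an encounter-level signal by counting flagged
notes against all notes linked to the admission.  The fraction feeds
inclusive thresholds at 10%, 25% and 50% ("present in at least 10% of
notes"), which are nested by construction: ge50 implies ge25 implies ge10
implies any.  ICD-10 flags fire on prefix membership of canonicalized
codes, separately for the visit's top-5 discharge codes and for the
patient's full chart history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .corpus import Encounter, REVIEWED_NOTE_TYPES, code_matches
from .lexicon import Lexicon
from .matcher import NoteFlag, classify_note

logger = logging.getLogger("pwudflag")

THRESHOLDS = (0.10, 0.25, 0.50)

# ICD-10 categories for substance use involving opioids, cocaine,
# stimulants/other psychoactive substances (category-level prefixes).
DEFAULT_CODE_LIST = frozenset({"F11", "F14", "F15", "F19"})

SIGNAL_COLUMNS = [
    "encounter_id",
    "n_notes",
    "n_flagged_regex",
    "n_flagged_context",
    "fraction_regex",
    "regex_any",
    "regex_ge10",
    "regex_ge25",
    "regex_ge50",
    "context_any",
    "icd_visit",
    "icd_history",
]


@dataclass(frozen=True)
class EncounterSignal:
    encounter_id: str
    n_notes: int
    n_flagged_regex: int
    n_flagged_context: int
    fraction_regex: float
    regex_any: bool
    regex_ge10: bool
    regex_ge25: bool
    regex_ge50: bool
    context_any: bool
    icd_visit: bool
    icd_history: bool


def aggregate_encounter(
    encounter_id: str,
    regex_flags: list[NoteFlag],
    context_flags: list[NoteFlag],
    n_notes_linked: int,
    icd_visit: bool = False,
    icd_history: bool = False,
) -> EncounterSignal:
    """Combine note flags into one EncounterSignal.

    ``n_notes_linked`` is the denominator (all notes linked to the
    admission); zero-note encounters get fraction 0 and all text flags
    false — they cannot be identified from text.
    """
    if n_notes_linked < max(len(regex_flags), len(context_flags)):
        raise ValueError(
            f"{encounter_id}: n_notes_linked={n_notes_linked} < number of note flags"
        )
    if n_notes_linked == 0 and (regex_flags or context_flags):
        raise ValueError(f"{encounter_id}: zero linked notes but note flags supplied")
    n_regex = sum(1 for f in regex_flags if f.flagged)
    n_context = sum(1 for f in context_flags if f.flagged)
    fraction = n_regex / n_notes_linked if n_notes_linked > 0 else 0.0
    return EncounterSignal(
        encounter_id=encounter_id,
        n_notes=n_notes_linked,
        n_flagged_regex=n_regex,
        n_flagged_context=n_context,
        fraction_regex=fraction,
        regex_any=n_regex >= 1,
        regex_ge10=n_notes_linked > 0 and fraction >= THRESHOLDS[0],
        regex_ge25=n_notes_linked > 0 and fraction >= THRESHOLDS[1],
        regex_ge50=n_notes_linked > 0 and fraction >= THRESHOLDS[2],
        context_any=n_context >= 1,
        icd_visit=icd_visit,
        icd_history=icd_history,
    )


def flag_icd(encounter: Encounter, code_list, scope: str) -> bool:
    """True when any code in the scope has a canonical prefix in code_list."""
    if not code_list:
        raise ValueError("empty ICD-10 code list")
    if scope == "visit":
        codes = encounter.visit_codes
    elif scope == "history":
        codes = encounter.history_codes
    else:
        raise ValueError(f"unknown ICD scope {scope!r}")
    return any(code_matches(c, frozenset(code_list)) for c in codes)


def build_signals(
    encounters: list[Encounter],
    lexicon: Lexicon,
    code_list=DEFAULT_CODE_LIST,
    restrict_note_types: bool = False,
    count_historical_as_positive: bool = True,
) -> pd.DataFrame:
    """One EncounterSignal row per encounter.

    ``restrict_note_types`` limits both numerator and denominator to the
    three reviewed note types (emergency, hpi, discharge); by default all
    linked notes count.
    """
    rows = []
    for enc in encounters:
        notes = enc.notes
        if restrict_note_types:
            notes = [n for n in notes if n.note_type in REVIEWED_NOTE_TYPES]
        if len(enc.visit_codes) > 5:
            logger.warning(
                "encounter %s has %d visit codes (expected top-5 list)",
                enc.encounter_id,
                len(enc.visit_codes),
            )
        regex_flags = [classify_note(n, lexicon, "regex") for n in notes]
        context_flags = [
            classify_note(n, lexicon, "context", count_historical_as_positive)
            for n in notes
        ]
        sig = aggregate_encounter(
            enc.encounter_id,
            regex_flags,
            context_flags,
            n_notes_linked=len(notes),
            icd_visit=flag_icd(enc, code_list, "visit"),
            icd_history=flag_icd(enc, code_list, "history"),
        )
        rows.append(sig)
    return pd.DataFrame([vars(s) for s in rows], columns=SIGNAL_COLUMNS)


def write_signals(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_signals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in df.columns:
        if col.startswith(("regex_", "context_", "icd_")):
            df[col] = df[col].astype(bool)
    df["encounter_id"] = df["encounter_id"].astype(str)
    return df
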