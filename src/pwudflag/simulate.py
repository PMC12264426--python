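"""Synthetic encounter corpora with known ground truth.

Generates a cohort of hospital encounters with a configurable prevalence
of true PWUD status, per-encounter note counts, note-type mix, and
per-note probabilities of (a) a genuine drug-use phrase in PWUD
encounters, (b) a negated mention ("Denies heroin use.") in any
encounter, and (c) a clinical false trigger ("Fentanyl gtt titrated.") in
any encounter.  Visit-level ICD-10 codes are assigned with configurable
sensitivity and specificity against the true label; history codes are a
superset of visit codes plus extras, so the history flag fires at least
as often as the visit flag.

The generator writes the same notes.jsonl / codes.csv / labels.csv files
the pipeline reads, plus a truth.csv sidecar that no pipeline stage ever
consumes (leakage is prevented by interface: the pipeline sees only
notes and codes).

The default configuration is a stylized emulation of a chart-review
subcohort: 790 encounters, prevalence 0.067, Poisson(3)-with-minimum-1
notes per encounter.  It mimics the shape of such a cohort, not any real
hospital's data.

``expected_encounter_sensitivity`` gives the closed-form companion
P(at least one note flagged | PWUD) = 1 - E[(1 - p_mention)^K] for
parameter-recovery testing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .corpus import (
    Encounter,
    GoldLabel,
    NOT_PWUD,
    NOTE_TYPES,
    Note,
    PWUD,
    write_codes,
    write_labels,
    write_notes,
)
from .lexicon import Lexicon, default_lexicon
from .matcher import annotate

# Roles a generated note can play.
ROLE_PWUD_MENTION = "pwud_mention"
ROLE_NEGATED_ONLY = "negated_only"
ROLE_FALSE_TRIGGER_ONLY = "false_trigger_only"
ROLE_NEUTRAL = "neutral"

DRUG_USE_CODE = "F11.20"          # opioid dependence, uncomplicated
EXTRA_HISTORY_CODE = "F14.10"     # cocaine abuse, uncomplicated
NEUTRAL_VISIT_CODES = ("I10", "E11.9", "J18.9", "N39.0", "K21.9")
NEUTRAL_HISTORY_CODES = ("E78.5", "M54.5", "Z87.891")


@dataclass(frozen=True)
class NotesPerEncounter:
    """Note-count distribution: fixed k, or Poisson(mean) truncated below at minimum."""

    kind: str = "poisson"          # "poisson" | "fixed"
    mean: float = 3.0
    fixed: int = 3
    minimum: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "fixed"):
            raise ValueError(f"unknown notes-per-encounter kind {self.kind!r}")
        if self.kind == "poisson" and self.mean <= 0:
            raise ValueError("poisson mean must be > 0")
        if self.kind == "fixed" and self.fixed < 0:
            raise ValueError("fixed note count must be >= 0")
        if self.minimum < 0:
            raise ValueError("minimum must be >= 0")

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return max(self.fixed, self.minimum)
        return max(int(rng.poisson(self.mean)), self.minimum)

    def pmf_truncated(self, kmax: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Support and probabilities of K = max(draw, minimum), to numerical exhaustion."""
        if self.kind == "fixed":
            k = max(self.fixed, self.minimum)
            return np.array([k]), np.array([1.0])
        if kmax is None:
            kmax = int(stats.poisson.ppf(1 - 1e-12, self.mean)) + 1
        ks = np.arange(self.minimum, kmax + 1)
        probs = stats.poisson.pmf(ks, self.mean)
        # mass at or below the floor collapses onto the floor
        probs[0] = stats.poisson.cdf(self.minimum, self.mean)
        return ks, probs


@dataclass
class GeneratorConfig:
    n_encounters: int = 790
    prevalence: float = 0.067
    notes_per_encounter: NotesPerEncounter = field(default_factory=NotesPerEncounter)
    note_type_mix: dict[str, float] = field(
        default_factory=lambda: {"emergency": 0.2, "hpi": 0.25, "discharge": 0.25, "other": 0.3}
    )
    p_mention: float = 0.5
    p_negated_mention: float = 0.05
    p_false_trigger: float = 0.05
    icd_sensitivity: float = 0.434
    icd_specificity: float = 0.995
    history_extra_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be >= 1")
        for name in (
            "prevalence",
            "p_mention",
            "p_negated_mention",
            "p_false_trigger",
            "icd_sensitivity",
            "icd_specificity",
            "history_extra_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        mix_keys = set(self.note_type_mix)
        if not mix_keys.issubset(NOTE_TYPES):
            raise ValueError(f"unknown note types in mix: {sorted(mix_keys - set(NOTE_TYPES))}")
        total = sum(self.note_type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"note_type_mix sums to {total}, not 1")


@dataclass
class PhraseBank:
    """Sentence templates used to compose synthetic note text.

    Every positive phrase must hit at least one lexicon term as a true
    (non-negated, non-false-trigger) match; every negated phrase must hit
    only as negated; every false-trigger phrase only as a false trigger;
    filler sentences must hit nothing.  ``validate`` enforces all four.
    """

    positive_phrases: list[str] = field(
        default_factory=lambda: [
            "Patient injects drugs on a daily basis.",
            "She is an intravenous drug user per previous records.",
            "Reports ongoing heroin use this month.",
            "Admits to recent cocaine use before arrival.",
            "Known IVDU with track marks on exam.",
            "Uses methamphetamine several times weekly.",
        ]
    )
    negated_phrases: list[str] = field(
        default_factory=lambda: [
            "No IVDU reported by the patient.",
            "Denies heroin or any recreational substances.",
            "Denies cocaine use at this time.",
            "Negative for methamphetamine on interview.",
        ]
    )
    false_trigger_phrases: list[str] = field(
        default_factory=lambda: [
            "Fentanyl gtt titrated for sedation.",
            "Started fentanyl drip in the ICU.",
            "Fentanyl patch applied for chronic pain.",
            "Receiving fentanyl infusion per protocol.",
        ]
    )
    filler_sentences: list[str] = field(
        default_factory=lambda: [
            "Vital signs stable on arrival.",
            "Lungs clear to auscultation bilaterally.",
            "Abdomen soft and nontender.",
            "Plan to continue current management.",
            "Patient resting comfortably in bed.",
            "Electrolytes within normal limits.",
            "Follow up with primary care in two weeks.",
            "No acute distress observed on exam.",
        ]
    )

    def validate(self, lexicon: Lexicon) -> None:
        for s in self.positive_phrases:
            hits = annotate(s, lexicon)
            if not any(h.is_true_hit for h in hits):
                raise ValueError(f"positive phrase has no true lexicon hit: {s!r}")
        for s in self.negated_phrases:
            hits = annotate(s, lexicon)
            if not hits or not all(h.negated for h in hits):
                raise ValueError(f"negated phrase must hit only as negated: {s!r}")
        for s in self.false_trigger_phrases:
            hits = annotate(s, lexicon)
            if not hits or not all(h.false_trigger and not h.negated for h in hits):
                raise ValueError(f"false-trigger phrase must hit only as false trigger: {s!r}")
        for s in self.filler_sentences:
            if annotate(s, lexicon):
                raise ValueError(f"filler sentence matches the lexicon: {s!r}")


def generate_note(
    role: str,
    note_type: str,
    bank: PhraseBank,
    rng: np.random.Generator,
    note_id: str = "n0",
    encounter_id: str = "e0",
) -> Note:
    """Compose one note for the requested role.

    The special sentence (positive / negated / false-trigger) is placed
    among 1-3 filler sentences at a random position.
    """
    n_filler = int(rng.integers(1, 4))
    sentences = [str(rng.choice(bank.filler_sentences)) for _ in range(n_filler)]
    if role == ROLE_PWUD_MENTION:
        special = str(rng.choice(bank.positive_phrases))
    elif role == ROLE_NEGATED_ONLY:
        special = str(rng.choice(bank.negated_phrases))
    elif role == ROLE_FALSE_TRIGGER_ONLY:
        special = str(rng.choice(bank.false_trigger_phrases))
    elif role == ROLE_NEUTRAL:
        special = None
    else:
        raise ValueError(f"unknown note role {role!r}")
    if special is not None:
        sentences.insert(int(rng.integers(0, len(sentences) + 1)), special)
    return Note(note_id, encounter_id, note_type, " ".join(sentences))


def _note_role(is_pwud: bool, cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[str, dict]:
    """Role of one note; mention beats negation beats false trigger when several fire."""
    events = {
        "mention": is_pwud and rng.random() < cfg.p_mention,
        "negated": rng.random() < cfg.p_negated_mention,
        "false_trigger": rng.random() < cfg.p_false_trigger,
    }
    if events["mention"]:
        role = ROLE_PWUD_MENTION
    elif events["negated"]:
        role = ROLE_NEGATED_ONLY
    elif events["false_trigger"]:
        role = ROLE_FALSE_TRIGGER_ONLY
    else:
        role = ROLE_NEUTRAL
    return role, events


def generate_corpus(
    config: GeneratorConfig,
    bank: PhraseBank | None = None,
    lexicon: Lexicon | None = None,
) -> tuple[list[Encounter], dict[str, GoldLabel], list[dict]]:
    """Draw a full synthetic cohort.

    Returns (encounters, gold label map, truth sidecar records).  The
    sidecar records per-encounter truth (label, per-note roles, whether
    the drug-use ICD-10 code was assigned) and exists only for audit and
    testing; the pipeline itself consumes only notes and codes.
    """
    lexicon = lexicon or default_lexicon()
    bank = bank or PhraseBank()
    bank.validate(lexicon)
    rng = np.random.default_rng(config.seed)

    type_names = list(config.note_type_mix)
    type_probs = np.array([config.note_type_mix[t] for t in type_names], dtype=float)
    type_probs = type_probs / type_probs.sum()

    encounters: list[Encounter] = []
    gold: dict[str, GoldLabel] = {}
    truth: list[dict] = []
    width = len(str(config.n_encounters))
    for i in range(config.n_encounters):
        eid = f"E{i:0{width}d}"
        is_pwud = bool(rng.random() < config.prevalence)
        n_notes = config.notes_per_encounter.sample(rng)
        notes, roles = [], []
        for j in range(n_notes):
            note_type = str(type_names[rng.choice(len(type_names), p=type_probs)])
            role, _ = _note_role(is_pwud, config, rng)
            notes.append(
                generate_note(role, note_type, bank, rng, f"{eid}-N{j}", eid)
            )
            roles.append(role)

        # visit-level ICD-10 codes with configured accuracy
        if is_pwud:
            icd_assigned = bool(rng.random() < config.icd_sensitivity)
        else:
            icd_assigned = bool(rng.random() >= config.icd_specificity)
        visit = [str(rng.choice(NEUTRAL_VISIT_CODES)) for _ in range(int(rng.integers(1, 4)))]
        if icd_assigned:
            visit.insert(int(rng.integers(0, len(visit) + 1)), DRUG_USE_CODE)
        history = list(visit) + [str(rng.choice(NEUTRAL_HISTORY_CODES))]
        history_extra = bool(rng.random() < config.history_extra_rate)
        if history_extra:
            history.append(EXTRA_HISTORY_CODE)

        encounters.append(
            Encounter(eid, patient_id=f"P{i:0{width}d}", visit_codes=visit,
                      history_codes=history, notes=notes)
        )
        gold[eid] = GoldLabel(eid, PWUD if is_pwud else NOT_PWUD)
        truth.append(
            {
                "encounter_id": eid,
                "true_label": PWUD if is_pwud else NOT_PWUD,
                "n_notes": n_notes,
                "note_roles": "|".join(roles),
                "icd_drug_code_assigned": int(icd_assigned),
                "history_extra_code": int(history_extra),
            }
        )
    return encounters, gold, truth


def write_corpus(
    encounters: list[Encounter],
    gold: dict[str, GoldLabel],
    truth: list[dict],
    out_dir,
) -> None:
    """Write notes.jsonl, codes.csv, labels.csv and truth.csv to out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_notes([n for e in encounters for n in e.notes], out / "notes.jsonl")
    write_codes({e.encounter_id: (e.visit_codes, e.history_codes) for e in encounters},
                out / "codes.csv")
    write_labels(gold, out / "labels.csv")
    with open(out / "truth.csv", "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(truth[0].keys()))
        w.writeheader()
        w.writerows(truth)


def expected_encounter_sensitivity(config: GeneratorConfig) -> float:
    """Closed-form P(regex-any flags a PWUD encounter) under the config.

    Each note of a PWUD encounter independently carries a true mention
    with probability p_mention, so
    P(flagged) = 1 - E[(1 - p_mention)^K] over the note-count law K.
    """
    ks, probs = config.notes_per_encounter.pmf_truncated()
    q = 1.0 - config.p_mention
    return float(1.0 - np.sum(probs * np.power(q, ks.astype(float))))


def load_config(path) -> GeneratorConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    npe = raw.pop("notes_per_encounter", None)
    cfg = GeneratorConfig(**raw)
    if npe is not None:
        cfg.notes_per_encounter = NotesPerEncounter(**npe)
    return cfg
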