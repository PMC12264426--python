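"""Lexicon data model: terms, negation cues, false-trigger rules.

A lexicon is the curated list of words and phrases whose occurrence flags a
clinical note as describing drug use.  Terms fall into three categories —
the *action* of drug use ("injects drugs"), the *person* ("intravenous drug
user", "IVDU"), and *drugs* themselves ("heroin", "cocaine").  Because drug
names also appear in legitimate medication contexts, the lexicon carries
false-trigger rules (e.g. "fentanyl gtt" is an infusion, not drug use) and
negation cues ("no", "denies") with bounded character scopes.

The default lexicon shipped here is seeded from the terms named in the
methods literature; institutions are expected to supply their own list via
``load_lexicon`` — the term list is data, not algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

TERM_CATEGORIES = ("action", "person", "drug")
CUE_DIRECTIONS = ("before", "after")


@dataclass(frozen=True)
class TermPattern:
    """A single lexicon entry.

    ``pattern`` is a literal word or phrase; matching is case-insensitive,
    word-boundary anchored, and internal whitespace matches any run of
    whitespace or hyphens ("intravenous drug user" also hits
    "intravenous-drug user").
    """

    term_id: str
    pattern: str
    category: str

    def __post_init__(self) -> None:
        if not self.pattern.strip():
            raise ValueError(f"term {self.term_id!r}: empty pattern")
        if self.category not in TERM_CATEGORIES:
            raise ValueError(
                f"term {self.term_id!r}: category {self.category!r} "
                f"not in {TERM_CATEGORIES}"
            )


@dataclass(frozen=True)
class NegationCue:
    """A negation (or history) cue with a character scope window.

    ``window`` is the number of characters around the matched term within
    which the cue negates it; the scope never crosses a sentence boundary.
    """

    pattern: str
    window: int = 30
    direction: str = "before"

    def __post_init__(self) -> None:
        if not self.pattern.strip():
            raise ValueError("empty cue pattern")
        if self.window < 0:
            raise ValueError("cue window must be >= 0")
        if self.direction not in CUE_DIRECTIONS:
            raise ValueError(f"cue direction {self.direction!r} not in {CUE_DIRECTIONS}")


@dataclass(frozen=True)
class FalseTriggerRule:
    """Adjacent-text exclusion for a term, e.g. ('fentanyl', 'gtt' after)."""

    term_id: str
    pattern: str
    window: int = 15
    direction: str = "after"

    def __post_init__(self) -> None:
        if not self.pattern.strip():
            raise ValueError("empty false-trigger pattern")
        if self.window < 0:
            raise ValueError("false-trigger window must be >= 0")
        if self.direction not in CUE_DIRECTIONS:
            raise ValueError(
                f"false-trigger direction {self.direction!r} not in {CUE_DIRECTIONS}"
            )


@dataclass
class Lexicon:
    terms: list[TermPattern]
    negation_cues: list[NegationCue] = field(default_factory=list)
    false_trigger_rules: list[FalseTriggerRule] = field(default_factory=list)
    history_cues: list[NegationCue] = field(default_factory=list)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("lexicon must contain at least one term")
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate term_id in lexicon")
        known = set(ids)
        for rule in self.false_trigger_rules:
            if rule.term_id not in known:
                raise ValueError(
                    f"false-trigger rule references unknown term {rule.term_id!r}"
                )

    def term(self, term_id: str) -> TermPattern:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)

    def rules_for(self, term_id: str) -> list[FalseTriggerRule]:
        return [r for r in self.false_trigger_rules if r.term_id == term_id]


def default_lexicon() -> Lexicon:
    """Built-in starter lexicon covering all three term categories.

    Users should replace this with their institution's curated list; it
    exists so the pipeline is runnable and testable out of the box.
    """
    terms = [
        TermPattern("injects_drugs", "injects drugs", "action"),
        TermPattern("injection_drug_use", "injection drug use", "action"),
        TermPattern("iv_drug_use", "iv drug use", "action"),
        TermPattern("smoked_crack", "smoked crack", "action"),
        TermPattern("snorts", "snorts", "action"),
        TermPattern("snorting", "snorting", "action"),
        TermPattern("sniffs", "sniffs", "action"),
        TermPattern("intravenous_drug_user", "intravenous drug user", "person"),
        TermPattern("ivdu", "IVDU", "person"),
        TermPattern("pwid", "person who injects drugs", "person"),
        TermPattern("heroin", "heroin", "drug"),
        TermPattern("cocaine", "cocaine", "drug"),
        TermPattern("fentanyl", "fentanyl", "drug"),
        TermPattern("methamphetamine", "methamphetamine", "drug"),
        TermPattern("crack_cocaine", "crack cocaine", "drug"),
    ]
    negation_cues = [
        NegationCue("no"),
        NegationCue("denies"),
        NegationCue("denied"),
        NegationCue("negative for"),
        NegationCue("without"),
        NegationCue("not"),
    ]
    history_cues = [
        NegationCue("history of"),
        NegationCue("h/o"),
        NegationCue("prior"),
        NegationCue("remote"),
    ]
    # medication-administration contexts for drug-name terms
    med_contexts = ("gtt", "drip", "patch", "mcg", "infusion", "prn")
    false_triggers = [
        FalseTriggerRule(t.term_id, ctx)
        for t in terms
        if t.category == "drug"
        for ctx in med_contexts
    ]
    return Lexicon(
        terms=terms,
        negation_cues=negation_cues,
        false_trigger_rules=false_triggers,
        history_cues=history_cues,
        version="builtin-1",
    )


def _cues_from_yaml(raw: list | None, default_window: int, default_dir: str) -> list[NegationCue]:
    out = []
    for item in raw or []:
        if isinstance(item, str):
            out.append(NegationCue(item, default_window, default_dir))
        else:
            out.append(
                NegationCue(
                    item["pattern"],
                    int(item.get("window", default_window)),
                    item.get("direction", default_dir),
                )
            )
    return out


def load_lexicon(path) -> Lexicon:
    """Read a lexicon from YAML (terms, negation_cues, false_triggers, history_cues)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    terms = [
        TermPattern(t["id"], t["pattern"], t["category"]) for t in raw.get("terms", [])
    ]
    false_triggers = [
        FalseTriggerRule(
            r["term_id"],
            r["pattern"],
            int(r.get("window", 15)),
            r.get("direction", "after"),
        )
        for r in raw.get("false_triggers", [])
    ]
    return Lexicon(
        terms=terms,
        negation_cues=_cues_from_yaml(raw.get("negation_cues"), 30, "before"),
        false_trigger_rules=false_triggers,
        history_cues=_cues_from_yaml(raw.get("history_cues"), 30, "before"),
        version=str(raw.get("version", "unversioned")),
    )


def save_lexicon(lexicon: Lexicon, path) -> None:
    raw = {
        "version": lexicon.version,
        "terms": [
            {"id": t.term_id, "pattern": t.pattern, "category": t.category}
            for t in lexicon.terms
        ],
        "negation_cues": [
            {"pattern": c.pattern, "window": c.window, "direction": c.direction}
            for c in lexicon.negation_cues
        ],
        "false_triggers": [
            {
                "term_id": r.term_id,
                "pattern": r.pattern,
                "window": r.window,
                "direction": r.direction,
            }
            for r in lexicon.false_trigger_rules
        ],
        "history_cues": [
            {"pattern": c.pattern, "window": c.window, "direction": c.direction}
            for c in lexicon.history_cues
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False, allow_unicode=True)
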