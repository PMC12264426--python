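"""Lexicon matching with assertion attributes and context snippets.

Two annotators share one matching engine:

* ``regex`` — pattern matching refined with negation elimination and
  false-trigger exclusion (a drug name followed by a medication context
  such as "fentanyl gtt" is a false trigger, not drug use).
* ``context`` — a ConText-style assertion annotator that reports, for
  every match, whether the mention is negated and whether it is
  historical ("history of IV drug use"); it emulates the outputs of the
  UIMA-based Open Health NLP toolkit without porting its internals.

Matching is case-insensitive and word-boundary anchored; internal
whitespace in a phrase pattern matches any run of whitespace or hyphens.
Offsets are 0-based half-open in Unicode code points.  Negation scope is
a bounded character window that never crosses a sentence boundary
(sentences split on ``.;!?`` or newline).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .corpus import Note
from .lexicon import Lexicon, NegationCue, TermPattern

SENTENCE_BREAK = re.compile(r"[.;!?\n]")

DEFAULT_SNIPPET_CHARS = 100


@dataclass(frozen=True)
class RawMatch:
    term_id: str
    start: int
    end: int
    matched_text: str


@dataclass(frozen=True)
class AssertedMatch:
    raw: RawMatch
    negated: bool
    historical: bool
    false_trigger: bool
    snippet: str

    @property
    def is_true_hit(self) -> bool:
        return not self.negated and not self.false_trigger


@dataclass(frozen=True)
class NoteFlag:
    note_id: str
    system: str
    n_matches_total: int
    n_matches_true: int

    @property
    def flagged(self) -> bool:
        return self.n_matches_true >= 1


def _compile_term(term: TermPattern) -> re.Pattern:
    parts = term.pattern.split()
    body = r"[\s\-]+".join(re.escape(p) for p in parts)
    return re.compile(rf"(?<!\w){body}(?!\w)", re.IGNORECASE)


_TERM_CACHE: dict[tuple[str, str], re.Pattern] = {}


def _term_regex(term: TermPattern) -> re.Pattern:
    key = (term.term_id, term.pattern)
    pat = _TERM_CACHE.get(key)
    if pat is None:
        pat = _TERM_CACHE[key] = _compile_term(term)
    return pat


def find_matches(text: str, lexicon: Lexicon) -> list[RawMatch]:
    """All lexicon term occurrences in ``text``.

    Per term, matches are non-overlapping (regex leftmost scan); matches of
    different terms may overlap and are all reported.  Sorted by start
    offset, then end, then term_id for determinism.
    """
    matches: list[RawMatch] = []
    for term in lexicon.terms:
        for m in _term_regex(term).finditer(text):
            matches.append(RawMatch(term.term_id, m.start(), m.end(), m.group(0)))
    matches.sort(key=lambda r: (r.start, r.end, r.term_id))
    return matches


def extract_snippet(text: str, match: RawMatch, context_chars: int = DEFAULT_SNIPPET_CHARS) -> str:
    """The matched span plus up to ``context_chars`` characters each side.

    Truncated at text boundaries, never padded.
    """
    if context_chars < 0:
        raise ValueError("context_chars must be >= 0")
    if not (0 <= match.start < match.end <= len(text)):
        raise ValueError(f"match [{match.start},{match.end}) out of bounds for text")
    lo = max(0, match.start - context_chars)
    hi = min(len(text), match.end + context_chars)
    return text[lo:hi]


def _cue_in_scope(text: str, match: RawMatch, cue: NegationCue) -> bool:
    """Is the cue within its window of the match, in the same sentence?"""
    cue_re = _TERM_CACHE.get(("__cue__", cue.pattern))
    if cue_re is None:
        parts = cue.pattern.split()
        body = r"[\s\-]+".join(re.escape(p) for p in parts)
        cue_re = _TERM_CACHE[("__cue__", cue.pattern)] = re.compile(
            rf"(?<!\w){body}(?!\w)", re.IGNORECASE
        )
    if cue.direction == "before":
        lo = max(0, match.start - cue.window)
        region = text[lo:match.start]
        # scope must not cross a sentence boundary
        breaks = list(SENTENCE_BREAK.finditer(region))
        if breaks:
            region = region[breaks[-1].end():]
    else:
        hi = min(len(text), match.end + cue.window)
        region = text[match.end:hi]
        brk = SENTENCE_BREAK.search(region)
        if brk:
            region = region[: brk.start()]
    return cue_re.search(region) is not None


def _false_trigger(text: str, match: RawMatch, lexicon: Lexicon) -> bool:
    for rule in lexicon.rules_for(match.term_id):
        cue = NegationCue(rule.pattern, rule.window, rule.direction)
        if _cue_in_scope(text, match, cue):
            return True
    return False


def assert_match(
    text: str,
    match: RawMatch,
    lexicon: Lexicon,
    context_chars: int = DEFAULT_SNIPPET_CHARS,
) -> AssertedMatch:
    """Attach negation / history / false-trigger assertions and a snippet."""
    if not (0 <= match.start < match.end <= len(text)):
        raise ValueError(f"match [{match.start},{match.end}) out of bounds")
    negated = any(_cue_in_scope(text, match, cue) for cue in lexicon.negation_cues)
    historical = any(_cue_in_scope(text, match, cue) for cue in lexicon.history_cues)
    false_trigger = _false_trigger(text, match, lexicon)
    return AssertedMatch(
        raw=match,
        negated=negated,
        historical=historical,
        false_trigger=false_trigger,
        snippet=extract_snippet(text, match, context_chars),
    )


def annotate(
    text: str, lexicon: Lexicon, context_chars: int = DEFAULT_SNIPPET_CHARS
) -> list[AssertedMatch]:
    return [assert_match(text, m, lexicon, context_chars) for m in find_matches(text, lexicon)]


def classify_note(
    note: Note,
    lexicon: Lexicon,
    system: str = "regex",
    count_historical_as_positive: bool = True,
) -> NoteFlag:
    """Note-level flag: total matches and true (positive) hits.

    For the ``regex`` system a true hit is a match that is neither negated
    nor a false trigger.  For the ``context`` system a true hit is a
    non-negated match — the ConText-style annotator reports assertion
    attributes but performs no false-trigger filtering, so it is more
    sensitive and less specific.  Historical mentions count as positive by
    default (the history attribute is carried through separately);
    ``count_historical_as_positive=False`` excludes them for the context
    system.
    """
    if system not in ("regex", "context"):
        raise ValueError(f"unknown system {system!r}")
    asserted = annotate(note.text, lexicon)
    if system == "regex":
        n_true = sum(1 for a in asserted if a.is_true_hit)
    else:
        n_true = sum(
            1
            for a in asserted
            if not a.negated and (count_historical_as_positive or not a.historical)
        )
    return NoteFlag(note.note_id, system, len(asserted), n_true)
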