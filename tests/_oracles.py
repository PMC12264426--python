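"""Independent brute-force oracles used to cross-check the implementation.

Kept deliberately separate from the package: the matcher oracle is a
character-by-character sliding-window scan, not a regex, so agreement
with ``pwudflag.matcher.find_matches`` is a genuine two-route check.
"""

from __future__ import annotations

WORD_CHARS = set("abcdefghijklmnopqrstuvwxyz0123456789_")
GAP_CHARS = set(" \t\n\r-")


def _is_word_char(ch: str) -> bool:
    return ch.lower() in WORD_CHARS


def _match_at(text: str, i: int, pattern: str) -> int | None:
    """Length-flexible literal match of ``pattern`` at position i, or None.

    Single spaces in the pattern match any nonempty run of whitespace or
    hyphens in the text; everything else matches case-insensitively
    character by character.  Returns the end offset on success.
    """
    t = text.lower()
    p = pattern.lower()
    j, k = i, 0
    while k < len(p):
        if p[k] == " ":
            if j < len(t) and t[j] in GAP_CHARS:
                while j < len(t) and t[j] in GAP_CHARS:
                    j += 1
                k += 1
            else:
                return None
        else:
            if j < len(t) and t[j] == p[k]:
                j += 1
                k += 1
            else:
                return None
    return j


def brute_force_find(text: str, term_id: str, pattern: str) -> list[tuple[str, int, int]]:
    """All word-bounded, non-overlapping occurrences of one literal phrase."""
    pattern = " ".join(pattern.split())
    out = []
    i = 0
    while i < len(text):
        if i > 0 and _is_word_char(text[i - 1]):
            i += 1
            continue
        end = _match_at(text, i, pattern)
        if end is not None and (end == len(text) or not _is_word_char(text[end])):
            out.append((term_id, i, end))
            i = end
        else:
            i += 1
    return out


def brute_force_matches(text: str, lexicon) -> list[tuple[str, int, int]]:
    """Oracle counterpart of find_matches over a whole lexicon."""
    hits = []
    for term in lexicon.terms:
        hits.extend(brute_force_find(text, term.term_id, term.pattern))
    hits.sort(key=lambda h: (h[1], h[2], h[0]))
    return hits


def brute_force_confusion(pred: dict, gold_positive: dict) -> tuple[int, int, int, int]:
    """Per-subject recount of (tp, fp, fn, tn) from boolean maps."""
    tp = sum(1 for k in pred if pred[k] and gold_positive[k])
    fp = sum(1 for k in pred if pred[k] and not gold_positive[k])
    fn = sum(1 for k in pred if not pred[k] and gold_positive[k])
    tn = sum(1 for k in pred if not pred[k] and not gold_positive[k])
    return tp, fp, fn, tn
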