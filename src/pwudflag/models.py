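"""Boolean encounter-level classifier models.

Each model is a boolean formula over the encounter signal names
``icd, regex_any, regex_ge10, regex_ge25, regex_ge50, context_any`` with
AND/OR and parentheses.  ``icd`` resolves through the model's
``icd_scope``: the visit's top-5 codes, the patient's chart history, or
either.  The built-in registry holds the 15 combinations evaluated in
practice: each single indicator, ICD-10 OR/AND each text flag, the
three-way OR, ICD-10 AND (RegEx OR ConText), and ICD-10 OR/AND each
note-fraction threshold flag.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass

SIGNAL_NAMES = frozenset(
    {"icd", "regex_any", "regex_ge10", "regex_ge25", "regex_ge50", "context_any"}
)
ICD_SCOPES = ("visit", "history", "visit_or_history")


def _validate_expression(expression: str) -> ast.Expression:
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise ValueError(f"bad model expression {expression!r}: {exc}") from exc
    for node in ast.walk(tree):
        if isinstance(node, ast.Name):
            if node.id not in SIGNAL_NAMES:
                raise ValueError(
                    f"expression {expression!r} references unknown signal {node.id!r}"
                )
        elif not isinstance(node, (ast.Expression, ast.BoolOp, ast.And, ast.Or, ast.Load)):
            raise ValueError(
                f"expression {expression!r}: only and/or over signal names allowed"
            )
    return tree


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    expression: str
    icd_scope: str = "visit"
    label: str = ""

    def __post_init__(self) -> None:
        if self.icd_scope not in ICD_SCOPES:
            raise ValueError(f"bad icd_scope {self.icd_scope!r}")
        _validate_expression(self.expression)

    @property
    def referenced_signals(self) -> frozenset[str]:
        tree = _validate_expression(self.expression)
        return frozenset(
            n.id for n in ast.walk(tree) if isinstance(n, ast.Name)
        )


def predict(model: ModelSpec, signal) -> bool:
    """Evaluate the model on one encounter signal (mapping or object).

    ``signal`` must expose ``icd_visit``/``icd_history`` and every text
    flag the expression references; a missing field raises, naming it.
    """
    get = signal.get if hasattr(signal, "get") else lambda k, d=None: getattr(signal, k, d)

    def lookup(name: str) -> bool:
        if name == "icd":
            if model.icd_scope == "visit":
                keys = ["icd_visit"]
            elif model.icd_scope == "history":
                keys = ["icd_history"]
            else:
                keys = ["icd_visit", "icd_history"]
            vals = [get(k) for k in keys]
            if any(v is None for v in vals):
                missing = [k for k, v in zip(keys, vals) if v is None]
                raise KeyError(f"signal missing field(s) {missing} for model {model.model_id!r}")
            return any(bool(v) for v in vals)
        v = get(name)
        if v is None:
            raise KeyError(f"signal missing field {name!r} for model {model.model_id!r}")
        return bool(v)

    env = {name: lookup(name) for name in model.referenced_signals}
    return bool(eval(compile(_validate_expression(model.expression), "<model>", "eval"), {}, env))


def builtin_registry(icd_scope: str = "visit") -> list[ModelSpec]:
    """The 15 standard model combinations."""
    rows = [
        ("icd_only", "icd", "ICD-10 only"),
        ("regex_only", "regex_any", "RegEx only"),
        ("context_only", "context_any", "ConText (OHNLP-style) only"),
        ("icd_or_regex", "icd or regex_any", "ICD-10 or RegEx"),
        ("icd_and_regex", "icd and regex_any", "ICD-10 and RegEx"),
        ("icd_or_context", "icd or context_any", "ICD-10 or ConText"),
        ("icd_and_context", "icd and context_any", "ICD-10 and ConText"),
        ("icd_or_regex_or_context", "icd or regex_any or context_any",
         "ICD-10 or RegEx or ConText"),
        ("icd_and_regex_or_context", "icd and (regex_any or context_any)",
         "ICD-10 and (RegEx or ConText)"),
        ("icd_or_regex_ge10", "icd or regex_ge10", "ICD-10 or RegEx 10% threshold"),
        ("icd_and_regex_ge10", "icd and regex_ge10", "ICD-10 and RegEx 10% threshold"),
        ("icd_or_regex_ge25", "icd or regex_ge25", "ICD-10 or RegEx 25% threshold"),
        ("icd_and_regex_ge25", "icd and regex_ge25", "ICD-10 and RegEx 25% threshold"),
        ("icd_or_regex_ge50", "icd or regex_ge50", "ICD-10 or RegEx 50% threshold"),
        ("icd_and_regex_ge50", "icd and regex_ge50", "ICD-10 and RegEx 50% threshold"),
    ]
    return [ModelSpec(mid, expr, icd_scope, label) for mid, expr, label in rows]


def registry_from_mapping(mapping: dict[str, str], icd_scope: str = "visit") -> list[ModelSpec]:
    """Build a registry from an id -> expression mapping (e.g. models.yaml)."""
    ids = list(mapping)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate model ids")
    return [ModelSpec(mid, expr, icd_scope, mid) for mid, expr in mapping.items()]
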