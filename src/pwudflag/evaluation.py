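"""Gold-standard adjudication and evaluation statistics.

Covers the full evaluation stack for binary encounter classifiers:

* chart-review adjudication (positive when at least 2 of the 3 reviewed
  chart types describe drug use; reviewer disagreements settled by a
  tiebreaker),
* confusion matrices, sensitivity, specificity, and per-class F1,
* the population-weighted net reclassification index
  ``wNRI = rho * NRI_e + (1 - rho) * NRI_ne`` where
  ``NRI_e = P(up | event) - P(down | event)`` and
  ``NRI_ne = P(down | nonevent) - P(up | nonevent)``; *up* means
  reclassified toward drug use, *down* away from it, and ``rho`` is the
  prevalence of drug use in the population,
* the paired McNemar test on discordant classifications, and the
  conditional normal-approximation power of that test for a study that
  samples ``n_total`` encounters of which a fraction ``prevalence`` are
  truly PWUD, the paired sensitivity difference is ``delta`` and the
  discordant proportion among PWUD is ``psi``:

      power = Phi((d*sqrt(n) - z*sqrt(psi)) / sqrt(psi - d^2)) + opposite tail

  with ``n = round(n_total * prevalence)`` effective pairs, plus a
  Monte-Carlo estimator for cross-checking the approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import PWUD, NOT_PWUD, GoldLabel, REVIEWED_NOTE_TYPES
from .models import ModelSpec, predict

EXACT_MCNEMAR_MAX_DISCORDANT = 25


# ---------------------------------------------------------------- adjudication

def adjudicate_gold(
    per_chart_labels: dict[str, bool] | None = None,
    reviewer_labels: tuple[bool, bool] | None = None,
    tiebreaker: bool | None = None,
) -> str:
    """Encounter gold label from chart review.

    With per-chart labels, the encounter is positive when at least 2 of
    the 3 reviewed chart types (emergency, hpi/admission, discharge) are
    positive.  With two independent reviewer labels, agreement decides;
    disagreement requires the tiebreaker.  Reviewer labels, when given,
    take precedence (each reviewer already applied the chart rule).
    """
    if reviewer_labels is not None:
        a, b = reviewer_labels
        if a == b:
            return PWUD if a else NOT_PWUD
        if tiebreaker is None:
            raise ValueError("reviewers disagree and no tiebreaker label supplied")
        return PWUD if tiebreaker else NOT_PWUD
    if per_chart_labels is None:
        raise ValueError("need per_chart_labels or reviewer_labels")
    unknown = set(per_chart_labels) - set(REVIEWED_NOTE_TYPES)
    if unknown:
        raise ValueError(f"per-chart labels for unreviewed chart types: {sorted(unknown)}")
    n_pos = sum(1 for v in per_chart_labels.values() if v)
    return PWUD if n_pos >= 2 else NOT_PWUD


# -------------------------------------------------------------------- metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    f1_pos: float
    f1_neg: float


def _as_bool_label(label) -> bool:
    if isinstance(label, GoldLabel):
        return label.is_positive
    if isinstance(label, str):
        if label not in (PWUD, NOT_PWUD):
            raise ValueError(f"bad gold label {label!r}")
        return label == PWUD
    return bool(label)


def confusion(predictions: dict, gold: dict) -> ConfusionMatrix:
    """Cross-tabulate encounter predictions against gold labels."""
    if set(predictions) != set(gold):
        only_p = sorted(set(predictions) - set(gold))[:5]
        only_g = sorted(set(gold) - set(predictions))[:5]
        raise ValueError(
            f"prediction/gold key mismatch (pred-only e.g. {only_p}, gold-only e.g. {only_g})"
        )
    tp = fp = fn = tn = 0
    for eid, pred in predictions.items():
        truth = _as_bool_label(gold[eid])
        if truth:
            tp, fn = (tp + 1, fn) if pred else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pred else (fp, tn + 1)
    return ConfusionMatrix(tp, fp, fn, tn)


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Sensitivity, specificity and per-class F1.

    The negative-class F1 treats non-drug-use as the positive class of
    the complemented problem (tn plays the true-positive role).  An F1
    denominator of zero yields 0 by convention; an empty gold class is an
    error rather than a silent NaN.
    """
    if cm.tp + cm.fn == 0:
        raise ValueError("no gold-positive encounters: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise ValueError("no gold-negative encounters: specificity undefined")
    f1_pos_den = 2 * cm.tp + cm.fp + cm.fn
    f1_neg_den = 2 * cm.tn + cm.fn + cm.fp
    return MetricSet(
        sensitivity=cm.tp / (cm.tp + cm.fn),
        specificity=cm.tn / (cm.tn + cm.fp),
        f1_pos=2 * cm.tp / f1_pos_den if f1_pos_den else 0.0,
        f1_neg=2 * cm.tn / f1_neg_den if f1_neg_den else 0.0,
    )


# ------------------------------------------------------------------------ NRI

@dataclass(frozen=True)
class NRIResult:
    p_up_event: float
    p_down_event: float
    p_up_nonevent: float
    p_down_nonevent: float
    nri_e: float
    nri_ne: float
    rho: float
    wnri: float


def compute_nri(pred_old: dict, pred_new: dict, gold: dict, rho: float | None = None) -> NRIResult:
    """Net reclassification of ``pred_new`` against ``pred_old``.

    *up* = old-negative reclassified new-positive, *down* the reverse.
    ``rho`` defaults to the observed prevalence of gold positives.
    """
    if set(pred_old) != set(pred_new) or set(pred_old) != set(gold):
        raise ValueError("pred_old, pred_new and gold must share one key set")
    up_e = down_e = up_ne = down_ne = n_e = n_ne = 0
    for eid in pred_old:
        old, new = bool(pred_old[eid]), bool(pred_new[eid])
        if _as_bool_label(gold[eid]):
            n_e += 1
            up_e += (not old) and new
            down_e += old and (not new)
        else:
            n_ne += 1
            up_ne += (not old) and new
            down_ne += old and (not new)
    if n_e == 0 or n_ne == 0:
        raise ValueError("NRI needs at least one event and one nonevent")
    if rho is None:
        rho = n_e / (n_e + n_ne)
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    p_up_e, p_down_e = up_e / n_e, down_e / n_e
    p_up_ne, p_down_ne = up_ne / n_ne, down_ne / n_ne
    nri_e = p_up_e - p_down_e
    nri_ne = p_down_ne - p_up_ne
    return NRIResult(
        p_up_event=p_up_e,
        p_down_event=p_down_e,
        p_up_nonevent=p_up_ne,
        p_down_nonevent=p_down_ne,
        nri_e=nri_e,
        nri_ne=nri_ne,
        rho=rho,
        wnri=rho * nri_e + (1.0 - rho) * nri_ne,
    )


# -------------------------------------------------------------------- McNemar

@dataclass(frozen=True)
class McNemarResult:
    b: int
    c: int
    statistic: float
    p_value: float
    exact: bool


def mcnemar_test(pred_a: dict, pred_b: dict, gold_restriction: dict | None = None) -> McNemarResult:
    """Paired McNemar test between two classifiers on one cohort.

    ``b`` counts encounters positive under A only, ``c`` positive under B
    only.  With ``gold_restriction`` the comparison is restricted to
    gold-positive encounters (a paired sensitivity comparison).  The
    asymptotic chi-square statistic (b-c)^2/(b+c) is used when b+c >= 25;
    below that the exact two-sided binomial p-value 2*P(X <= min(b,c))
    with X ~ Binomial(b+c, 1/2).  b+c = 0 gives statistic 0, p = 1.
    """
    if set(pred_a) != set(pred_b):
        raise ValueError("pred_a and pred_b must share one key set")
    keys = set(pred_a)
    if gold_restriction is not None:
        keys = {k for k in keys if _as_bool_label(gold_restriction[k])}
    b = sum(1 for k in keys if bool(pred_a[k]) and not bool(pred_b[k]))
    c = sum(1 for k in keys if not bool(pred_a[k]) and bool(pred_b[k]))
    n_disc = b + c
    if n_disc == 0:
        return McNemarResult(0, 0, 0.0, 1.0, exact=True)
    statistic = (b - c) ** 2 / n_disc
    if n_disc < EXACT_MCNEMAR_MAX_DISCORDANT:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n_disc, 0.5))
        return McNemarResult(b, c, statistic, float(p), exact=True)
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(b, c, statistic, p, exact=False)


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a paired-sensitivity McNemar power analysis.

    ``prevalence_assumed`` is the *design* prevalence used to size the
    paired subgroup (distinct from the NRI weighting prevalence);
    ``delta`` the detectable difference in sensitivities; ``discordant``
    the proportion of discordant results among true PWUD.
    """

    n_total: int
    prevalence_assumed: float
    delta: float
    discordant: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 < self.prevalence_assumed < 1:
            raise ValueError("prevalence_assumed must be in (0, 1)")
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.delta > self.discordant:
            raise ValueError("infeasible design: |delta| cannot exceed discordant proportion")
        if self.discordant <= self.delta**2:
            raise ValueError("variance term nonpositive: need discordant > delta^2")
        if self.discordant > 1:
            raise ValueError("discordant proportion must be <= 1")

    @property
    def n_effective(self) -> int:
        """Paired sample size: PWUD encounters among n_total, rounded."""
        return int(round(self.n_total * self.prevalence_assumed))


def _rejects(b: np.ndarray, c: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized rejection indicator of the McNemar rule used by mcnemar_test.

    Exact two-sided binomial when b + c < 25, asymptotic chi-square above.
    """
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    n_disc = b + c
    safe = np.maximum(n_disc, 1.0)
    statistic = np.where(n_disc > 0, (b - c) ** 2 / safe, 0.0)
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    p_exact = np.where(
        n_disc > 0,
        np.minimum(1.0, 2.0 * stats.binom.cdf(np.minimum(b, c), safe, 0.5)),
        1.0,
    )
    return np.where(n_disc < EXACT_MCNEMAR_MAX_DISCORDANT, p_exact < alpha, statistic > crit)


def mcnemar_power(spec: PowerSpec, method: str = "exact") -> float:
    """Power of the two-sided paired McNemar design.

    ``method="exact"`` (default) enumerates the design exactly: the
    discordant count N_d among the n_effective pairs is Binomial(n, psi),
    and given N_d the first-only-positive count is Binomial(N_d,
    (psi + d) / (2 psi)); power sums the rejection probability of the
    same decision rule ``mcnemar_test`` applies (exact binomial test
    below 25 discordant pairs, chi-square above) over that joint law.
    ``method="approx"`` is the conditional normal approximation
    Phi((d sqrt(n) - z sqrt(psi)) / sqrt(psi - d^2)) plus the opposite
    tail; it overstates power when the expected discordant count is
    small (a few tens of pairs or fewer).
    """
    n = spec.n_effective
    if n < 1:
        raise ValueError("effective paired n is zero; increase n_total or prevalence")
    d, psi = spec.delta, spec.discordant
    if method == "approx":
        z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
        sd = np.sqrt(psi - d * d)
        upper = stats.norm.cdf((d * np.sqrt(n) - z * np.sqrt(psi)) / sd)
        lower = stats.norm.cdf((-d * np.sqrt(n) - z * np.sqrt(psi)) / sd)
        return float(upper + lower)
    if method != "exact":
        raise ValueError(f"unknown power method {method!r}")
    p1 = (psi + d) / (2.0 * psi) if psi > 0 else 0.5
    nds = np.arange(0, n + 1)
    weights = stats.binom.pmf(nds, n, psi)
    power = 0.0
    for nd, w in zip(nds, weights):
        if nd == 0 or w < 1e-16:
            continue
        bs = np.arange(0, nd + 1)
        rej = _rejects(bs, nd - bs, spec.alpha)
        power += w * float(np.sum(stats.binom.pmf(bs, nd, p1)[rej]))
    return float(power)


def simulate_mcnemar_power(spec: PowerSpec, reps: int = 100_000, seed: int | None = None) -> float:
    """Monte-Carlo power estimate under the same design.

    Each replicate draws the (b, c) discordant-cell counts for the
    ``n_effective`` paired PWUD encounters from a multinomial with cell
    probabilities (psi + d)/2 and (psi - d)/2, applies the same McNemar
    decision rule as ``mcnemar_test``, and counts rejections.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_effective
    d, psi = spec.delta, spec.discordant
    p10, p01 = (psi + d) / 2.0, (psi - d) / 2.0
    draws = rng.multinomial(n, [p10, p01, 1.0 - psi], size=reps)
    return float(np.mean(_rejects(draws[:, 0], draws[:, 1], spec.alpha)))


# ------------------------------------------------------------------ run study

def predictions_for_model(model: ModelSpec, signals: pd.DataFrame) -> dict[str, bool]:
    return {
        str(row["encounter_id"]): predict(model, row)
        for _, row in signals.iterrows()
    }


def run_study(
    signals: pd.DataFrame,
    gold: dict,
    registry: list[ModelSpec],
    rho: float | None = None,
    baseline_id: str = "icd_only",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy and reclassification tables over a model registry.

    Returns (accuracy_table, nri_table): one metrics row per model, and
    one NRI row per model against the ICD-10 visit-code baseline.  Full
    precision is kept; round only for display.
    """
    preds = {m.model_id: predictions_for_model(m, signals) for m in registry}
    if baseline_id not in preds:
        raise ValueError(f"baseline model {baseline_id!r} not in registry")
    acc_rows, nri_rows = [], []
    for m in registry:
        ms = metrics(confusion(preds[m.model_id], gold))
        acc_rows.append(
            {
                "model_id": m.model_id,
                "label": m.label or m.model_id,
                "sensitivity": ms.sensitivity,
                "specificity": ms.specificity,
                "f1_pos": ms.f1_pos,
                "f1_neg": ms.f1_neg,
            }
        )
        nri = compute_nri(preds[baseline_id], preds[m.model_id], gold, rho)
        nri_rows.append(
            {
                "model_id": m.model_id,
                "label": m.label or m.model_id,
                "wnri": nri.wnri,
                "nri_e": nri.nri_e,
                "nri_ne": nri.nri_ne,
                "rho_used": nri.rho,
            }
        )
    return pd.DataFrame(acc_rows), pd.DataFrame(nri_rows)
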