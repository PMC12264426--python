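# Methods

`pwudflag` implements a rule-based pipeline for identifying hospital
encounters of people who use drugs (PWUD) from clinical note text and
ICD-10 billing codes, together with the statistics used to evaluate and
compare such classifiers. This note records the model, the defaults, the
numerical conventions, and the design choices that were genuinely open.

## The classification problem

Injection and other non-prescribed drug use has no dedicated ICD-10 code,
and substance-use codes on claims data are both insensitive and applied
inconsistently. Free-text clinical notes mention drug use far more often
than billing data capture it, but raw keyword search over notes is noisy:
mentions are frequently negated ("denies heroin use") or clinically
irrelevant ("fentanyl gtt" is an infusion the hospital administered, not
drug use). The unit of classification is the *encounter* (one hospital
admission); notes and visit-level diagnosis codes attach to encounters,
and chart-history codes attach to the patient.

## Text matching and assertion

The lexicon is a curated list of literal words and phrases in three
categories — the action of drug use ("injects drugs"), the person
("intravenous drug user", "IVDU"), and drug names ("heroin", "cocaine").
Matching is case-insensitive and word-boundary anchored; internal
whitespace in a phrase matches any run of whitespace or hyphens, so
"intravenous-drug user" still hits. Offsets are 0-based half-open in
Unicode code points. Matches of one term never overlap (leftmost scan);
matches of different terms may.

Two annotators share this engine:

* **regex** — matches minus negated mentions minus false triggers. A
  match is negated when a negation cue ("no", "denies", "negative for",
  "without", "not") occurs within its scope window — 30 characters
  preceding the match by default, never crossing a sentence boundary
  (sentences split on `.;!?` or newline). A match is a false trigger
  when a term-specific adjacent pattern fires; the shipped rules mark a
  drug name followed within 15 characters by a medication context
  ("gtt", "drip", "patch", "mcg", "infusion", "prn").
* **context** — a ConText-style assertion annotator that reports, per
  match, a negation flag and a history flag ("history of", "h/o",
  "prior", "remote" in scope). It emulates the outputs of a UIMA-based
  clinical NLP toolkit without porting its internals, and applies **no**
  false-trigger filtering — its outputs are snippet, note type, term,
  history, negation. It is therefore more sensitive and less specific
  than the refined regex system, which is the qualitative behaviour such
  toolkits show in practice. Historical mentions count as positive by
  default; a switch excludes them.

The 30-character negation window and 15-character false-trigger window
are configurable; the defaults cover the common "no X" / "denies X" /
"X gtt" constructions without reaching across clauses. Cues after the
term ("IVDU: denied") are supported by the cue `direction` field but no
after-cues ship by default, since their behaviour in clinical text is
less predictable.

Snippets for human review are the matched span plus 100 characters of
context on each side, truncated at text boundaries and never padded.

## Encounter-level signals

A note is flagged when it has at least one true hit. Per encounter the
pipeline reports: note count, flagged-note counts for both systems, the
flagged fraction for the regex system, `any` flags, and inclusive
threshold flags at fractions ≥ 0.10, 0.25, 0.50 of notes. The
denominator is all notes linked to the admission by default; an option
restricts numerator and denominator to the three reviewed note types
(emergency, history-of-present-illness, discharge). Encounters with zero
notes get fraction 0 and all text flags false — they cannot be
identified from text. The threshold flags are nested by construction
(ge50 ⇒ ge25 ⇒ ge10 ⇒ any).

ICD-10 flags are computed separately for the visit's top-5 discharge
codes and the patient's chart history. Codes are canonicalized
(uppercase, dot stripped) and membership is prefix-based, so a
category-level list entry `F11` matches `F11.20`. The default code list
is `{F11, F14, F15, F19}` — opioid, cocaine, stimulant, and other
psychoactive substance use; users supply their institution's list for
real analyses.

## Classifier models

Fifteen boolean models over the signals `{icd, regex_any, regex_ge10,
regex_ge25, regex_ge50, context_any}`: each single indicator, ICD-10
OR/AND each text flag, the three-way OR, ICD-10 AND (RegEx OR ConText),
and ICD-10 OR/AND each threshold flag. `icd` resolves through the
model's scope (visit by default; history or either selectable). By
construction `A∧B ⇒ A ⇒ A∨B` pointwise, so sensitivity is ordered
OR ≥ single ≥ AND and specificity the reverse on any corpus — the suite
asserts this on random corpora.

## Evaluation statistics

**Gold standard.** An encounter is chart-review positive when at least 2
of the 3 reviewed chart types describe drug use; when two reviewer
encounter labels are supplied instead, agreement decides and a
disagreement requires a tiebreaker label (an error otherwise).

**Accuracy.** Sensitivity tp/(tp+fn), specificity tn/(tn+fp), and
per-class F1. The negative-class F1 is the F1 of the complement-labeled
problem (tn in the true-positive role); a zero F1 denominator yields 0
by convention, while an empty gold class raises rather than returning
NaN.

**Net reclassification.** Comparing a new classifier against a baseline
(ICD-10 visit codes by default): among gold events,
NRI_e = P(up) − P(down); among nonevents, NRI_ne = P(down) − P(up),
where *up* is reclassification toward drug use. The population-weighted
index is wNRI = ρ·NRI_e + (1−ρ)·NRI_ne with ρ the drug-use prevalence,
defaulting to the observed prevalence and overridable. The identity
holds to machine precision for every result, and OR-augmented models
have p_down_event = 0, hence NRI_e ≥ 0 and NRI_ne ≤ 0 (AND-restricted
models mirror this) — both asserted as properties.

**McNemar test.** For paired classifiers, b and c count the discordant
encounters. The statistic is (b−c)²/(b+c). With fewer than 25 discordant
pairs the p-value is the exact two-sided binomial 2·P(X ≤ min(b,c)),
X ~ Bin(b+c, ½), capped at 1; otherwise the asymptotic chi-square tail.
b+c = 0 gives statistic 0 and p = 1 by convention.

**Power.** A study that samples `n_total` encounters with design
prevalence π compares two search methods' sensitivities on the
n = round(n_total·π) truly-PWUD encounters. With discordant proportion
ψ among PWUD and sensitivity difference d, `mcnemar_power` offers:

* `method="exact"` (default): the discordant count N_d ~ Bin(n, ψ) and,
  given N_d, b ~ Bin(N_d, (ψ+d)/(2ψ)); power is the total probability of
  the rejection region of the same decision rule `mcnemar_test` uses.
  This is a deterministic enumeration, not a simulation.
* `method="approx"`: the conditional normal approximation
  Φ((d√n − z_{1−α/2}√ψ)/√(ψ−d²)) plus the negligible opposite tail.

The exact method is the default because the normal approximation is
visibly optimistic when the expected discordant count is small: at the
reference design (n_total = 790, π = 0.10, d = 0.15, ψ = 0.22,
α = 0.05, so n = 79 pairs and ≈17 expected discordant pairs) the
approximation gives 0.824 while exact enumeration — and the Monte-Carlo
estimator `simulate_mcnemar_power`, which draws the multinomial
discordant cells and applies the identical decision rule — both give
0.801. Enumeration and simulation are two routes to the same quantity
and agree within Monte-Carlo error; the approximation is retained for
comparison with standard power software. Designs with d > ψ or ψ ≤ d²
are rejected as infeasible.

## Synthetic corpora

The generator draws, per encounter: a true PWUD label at the configured
prevalence; a note count (Poisson with a floor, or fixed); a note type
from the configured mix; and per-note events — a genuine drug-use
sentence with probability `p_mention` (PWUD encounters only), a negated
mention with `p_negated_mention`, a false-trigger sentence with
`p_false_trigger` (both in any encounter, as realistic noise). Notes are
composed from a phrase bank of template sentences validated against the
lexicon at build time: positive phrases must produce a true hit, negated
phrases only negated hits, false-trigger phrases only false-trigger
hits, filler sentences no hits. Visit ICD-10 codes include a drug-use
code with probability `icd_sensitivity` for PWUD and `1 −
icd_specificity` otherwise, padded with neutral codes; history codes are
a superset of visit codes plus an extra substance-use code at
`history_extra_rate`, so the history flag fires at least as often as the
visit flag. A single integer seed drives one `numpy` Generator threaded
through all sampling; identical configurations regenerate byte-identical
corpora. A truth sidecar records per-encounter labels, note roles, and
code assignments for auditing; no pipeline stage reads it — the pipeline
consumes only the notes and codes files.

Defaults are a stylized emulation of a chart-review subcohort: 790
encounters, prevalence 0.067, Poisson(3)-with-floor-1 notes per
encounter (median 3), p_mention 0.5, negation and false-trigger rates
0.05, ICD visit sensitivity 0.434 and specificity 0.995 (typical
claims-code accuracy for substance use), history extras at 0.05. The
generator emulates the *statistical structure* such cohorts exhibit, not
real clinical prose: notes are short template compositions, there is no
inter-note correlation within an encounter beyond the shared label, no
temporal structure, and no misspellings or abbreviation variants.
Passing tests therefore demonstrate correctness of the pipeline's logic
and calibration of its statistics under known generating conditions —
not matcher performance on real EHR text, which depends on the
institution's lexicon.

The closed-form companion `expected_encounter_sensitivity` returns
P(≥1 note flagged | PWUD) = 1 − E[(1−p_mention)^K] under the note-count
law, enabling parameter recovery: on a balanced 5,000-encounter corpus
the full pipeline recovers this value and the configured ICD accuracies
within ±0.03. The recovery experiment uses a balanced design
(prevalence 0.5) so both classes contribute ≈2,500 encounters and the
±0.03 band sits at more than three binomial standard errors.

## Numerical conventions and degenerate inputs

Thresholds are inclusive (fraction ≥ 0.10). Rounding to 3 decimals
happens only in rendered reports; machine outputs keep full precision.
Unknown note types are coerced to `other` with a structured warning;
encounters without codes get empty code lists with a warning; label/
encounter mismatches are errors listing the offending ids. Model
expressions are parsed as Python `and`/`or` syntax over validated signal
names only. More than 5 visit codes is tolerated with a warning (the
top-5 selection is the data supplier's job; billing order is out of
scope here).

## Known limitations

No statistical or ML text classification, no UMLS/ontology mapping, no
spelling correction, no HL7/FHIR parsing, no confidence intervals for
NRI, no category-based (multi-threshold) NRI, no ROC analysis. The
shipped lexicon is a starter list; real deployments must supply their
institution's curated terms, negation cues and false-trigger rules.
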