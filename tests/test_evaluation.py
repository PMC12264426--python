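"""Adjudication, accuracy metrics, NRI, McNemar test and power."""

import numpy as np
import pytest
from scipy import stats

from _oracles import brute_force_confusion
from pwudflag.evaluation import (
    ConfusionMatrix,
    PowerSpec,
    adjudicate_gold,
    compute_nri,
    confusion,
    mcnemar_power,
    mcnemar_test,
    metrics,
    run_study,
    simulate_mcnemar_power,
)


class TestAdjudication:
    @pytest.mark.parametrize(
        "charts,expected",
        [
            ({"emergency": True, "hpi": True, "discharge": False}, "pwud"),
            ({"emergency": True, "hpi": False, "discharge": False}, "not_pwud"),
            ({"emergency": True, "hpi": True, "discharge": True}, "pwud"),
            ({"emergency": False, "hpi": False, "discharge": False}, "not_pwud"),
        ],
    )
    def test_two_of_three_chart_rule(self, charts, expected):
        assert adjudicate_gold(per_chart_labels=charts) == expected

    def test_reviewer_agreement_decides(self):
        assert adjudicate_gold(reviewer_labels=(True, True)) == "pwud"
        assert adjudicate_gold(reviewer_labels=(False, False)) == "not_pwud"

    def test_tiebreaker_resolves_disagreement(self):
        assert adjudicate_gold(reviewer_labels=(True, False), tiebreaker=True) == "pwud"
        assert adjudicate_gold(reviewer_labels=(False, True), tiebreaker=False) == "not_pwud"

    def test_disagreement_without_tiebreaker_rejected(self):
        with pytest.raises(ValueError, match="tiebreaker"):
            adjudicate_gold(reviewer_labels=(True, False))


class TestConfusionAndMetrics:
    def _maps(self, pred_bits, gold_bits):
        ids = [f"e{i}" for i in range(len(pred_bits))]
        return (
            dict(zip(ids, map(bool, pred_bits))),
            {i: "pwud" if g else "not_pwud" for i, g in zip(ids, gold_bits)},
        )

    def test_perfect_predictions(self):
        pred, gold = self._maps([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        cm = confusion(pred, gold)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (5, 5, 0, 0)
        ms = metrics(cm)
        assert ms.sensitivity == ms.specificity == ms.f1_pos == ms.f1_neg == 1.0

    def test_all_negative_predictor(self):
        pred, gold = self._maps([0] * 8, [1, 1, 1, 0, 0, 0, 0, 0])
        cm = confusion(pred, gold)
        assert cm.tp == 0 and cm.fn == 3

    def test_complement_predictor_swaps_cells(self):
        pred, gold = self._maps([1, 0, 1, 0, 1], [1, 1, 0, 0, 1])
        cm = confusion(pred, gold)
        comp = confusion({k: not v for k, v in pred.items()}, gold)
        assert (comp.tp, comp.fn, comp.fp, comp.tn) == (cm.fn, cm.tp, cm.tn, cm.fp)

    def test_key_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion({"a": True}, {"b": "pwud"})

    def test_sensitivity_specificity_arithmetic(self):
        ms = metrics(ConfusionMatrix(tp=9, fp=0, fn=1, tn=10))
        assert ms.sensitivity == pytest.approx(0.9)
        assert ms.specificity == pytest.approx(1.0)

    def test_f1_from_precision_recall_oracle(self):
        # independent route: harmonic mean of precision and recall
        cm = ConfusionMatrix(tp=3, fp=1, fn=1, tn=5)
        ms = metrics(cm)
        precision, recall = 3 / 4, 3 / 4
        assert ms.f1_pos == pytest.approx(2 * precision * recall / (precision + recall))
        assert ms.f1_pos == pytest.approx(0.75)

    def test_empty_gold_class_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(tp=0, fp=2, fn=0, tn=3))

    def test_confusion_agrees_with_per_subject_recount(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            gold_bits = rng.integers(0, 2, n)
            pred_bits = rng.integers(0, 2, n)
            pred, gold = self._maps(pred_bits, gold_bits)
            cm = confusion(pred, gold)
            gold_bool = {k: v == "pwud" for k, v in gold.items()}
            assert (cm.tp, cm.fp, cm.fn, cm.tn) == brute_force_confusion(pred, gold_bool)


class TestNRI:
    def test_identical_predictions_give_zero(self):
        pred = {"a": True, "b": False, "c": True}
        gold = {"a": "pwud", "b": "not_pwud", "c": "not_pwud"}
        r = compute_nri(pred, pred, gold)
        assert r.nri_e == r.nri_ne == r.wnri == 0.0

    def test_printed_formula_substitution(self):
        # rho=0.5, nri_e=0.2, nri_ne=-0.1 -> wnri=0.05 by direct substitution
        gold = {f"e{i}": "pwud" for i in range(10)}
        gold.update({f"n{i}": "not_pwud" for i in range(10)})
        old = {k: False for k in gold}
        new = dict(old)
        new["e0"] = new["e1"] = True          # 2/10 events up -> nri_e = 0.2
        new["n0"] = True                      # 1/10 nonevents up -> nri_ne = -0.1
        r = compute_nri(old, new, gold, rho=0.5)
        assert r.nri_e == pytest.approx(0.2)
        assert r.nri_ne == pytest.approx(-0.1)
        assert r.wnri == pytest.approx(0.05)

    def test_ten_subject_enumeration(self):
        # 4 events, 6 nonevents; new upgrades 2 events and 1 nonevent
        gold = {f"e{i}": "pwud" for i in range(4)}
        gold.update({f"n{i}": "not_pwud" for i in range(6)})
        old = {k: False for k in gold}
        new = dict(old, e0=True, e1=True, n0=True)
        r = compute_nri(old, new, gold)
        assert r.rho == pytest.approx(0.4)
        assert r.nri_e == pytest.approx(0.5)
        assert r.nri_ne == pytest.approx(-1 / 6)
        assert r.wnri == pytest.approx(0.4 * 0.5 + 0.6 * (-1 / 6)) == pytest.approx(0.1)

    def test_wnri_identity_on_random_cohorts(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            gold_bits = np.concatenate([[1, 0], rng.integers(0, 2, n - 2)])
            ids = [f"s{i}" for i in range(n)]
            gold = {i: "pwud" if g else "not_pwud" for i, g in zip(ids, gold_bits)}
            old = {i: bool(rng.integers(2)) for i in ids}
            new = {i: bool(rng.integers(2)) for i in ids}
            rho = float(rng.uniform())
            r = compute_nri(old, new, gold, rho)
            assert r.wnri == pytest.approx(rho * r.nri_e + (1 - rho) * r.nri_ne, abs=1e-15)

    def test_or_augmentation_direction(self):
        """new = old OR x can never reclassify downward."""
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = 20
            ids = [f"s{i}" for i in range(n)]
            gold_bits = np.concatenate([[1, 0], rng.integers(0, 2, n - 2)])
            gold = {i: "pwud" if g else "not_pwud" for i, g in zip(ids, gold_bits)}
            old = {i: bool(rng.integers(2)) for i in ids}
            x = {i: bool(rng.integers(2)) for i in ids}
            new = {i: old[i] or x[i] for i in ids}
            r = compute_nri(old, new, gold)
            assert r.p_down_event == 0 and r.nri_e >= 0 and r.nri_ne <= 0

    def test_no_events_rejected(self):
        gold = {"a": "not_pwud", "b": "not_pwud"}
        pred = {"a": False, "b": True}
        with pytest.raises(ValueError):
            compute_nri(pred, pred, gold)


class TestMcNemarTest:
    def _preds(self, b, c, n_both=3, n_neither=4):
        pred_a, pred_b = {}, {}
        k = 0
        for _ in range(b):
            pred_a[f"s{k}"], pred_b[f"s{k}"] = True, False
            k += 1
        for _ in range(c):
            pred_a[f"s{k}"], pred_b[f"s{k}"] = False, True
            k += 1
        for _ in range(n_both):
            pred_a[f"s{k}"], pred_b[f"s{k}"] = True, True
            k += 1
        for _ in range(n_neither):
            pred_a[f"s{k}"], pred_b[f"s{k}"] = False, False
            k += 1
        return pred_a, pred_b

    def test_symmetric_discordance(self):
        r = mcnemar_test(*self._preds(4, 4))
        assert r.statistic == 0 and r.p_value == pytest.approx(1.0)

    def test_no_discordance_convention(self):
        r = mcnemar_test(*self._preds(0, 0))
        assert r.statistic == 0 and r.p_value == 1.0

    def test_exact_small_sample(self):
        r = mcnemar_test(*self._preds(10, 2))
        assert r.statistic == pytest.approx((10 - 2) ** 2 / 12)
        assert r.exact
        assert r.p_value == pytest.approx(2 * stats.binom.cdf(2, 12, 0.5))

    def test_against_statsmodels_oracle(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for b, c in [(10, 2), (7, 5), (1, 0)]:
            r = mcnemar_test(*self._preds(b, c))
            table = [[0, b], [c, 0]]
            expected = sm.mcnemar(table, exact=True).pvalue
            assert r.p_value == pytest.approx(float(expected))

    def test_asymptotic_large_sample(self):
        r = mcnemar_test(*self._preds(30, 10))
        assert not r.exact
        assert r.statistic == pytest.approx(400 / 40)
        assert r.p_value == pytest.approx(float(stats.chi2.sf(10, 1)))

    def test_gold_restriction_limits_pairs(self):
        pred_a, pred_b = self._preds(2, 0, n_both=0, n_neither=2)
        gold = {k: ("pwud" if k in ("s0", "s1") else "not_pwud") for k in pred_a}
        r = mcnemar_test(pred_a, pred_b, gold_restriction=gold)
        assert (r.b, r.c) == (2, 0)


class TestPower:
    def test_exact_power_meets_design_target(self):
        spec = PowerSpec(790, 0.10, 0.15, 0.22, 0.05)
        assert spec.n_effective == 79
        assert mcnemar_power(spec) >= 0.80

    def test_approx_formula_value(self):
        # hand-computed: Phi((0.15*sqrt(79) - 1.95996*sqrt(0.22))/sqrt(0.1975))
        spec = PowerSpec(790, 0.10, 0.15, 0.22, 0.05)
        z = stats.norm.ppf(0.975)
        expect = stats.norm.cdf(
            (0.15 * np.sqrt(79) - z * np.sqrt(0.22)) / np.sqrt(0.22 - 0.15**2)
        ) + stats.norm.cdf(
            (-0.15 * np.sqrt(79) - z * np.sqrt(0.22)) / np.sqrt(0.22 - 0.15**2)
        )
        assert mcnemar_power(spec, "approx") == pytest.approx(float(expect))

    def test_null_power_close_to_alpha(self):
        spec = PowerSpec(790, 0.10, 0.0, 0.22, 0.05)
        assert mcnemar_power(spec, "approx") == pytest.approx(0.05, abs=0.01)
        # exact rule is conservative under the null, never anticonservative
        assert mcnemar_power(spec) <= 0.05 + 0.005

    def test_power_increases_with_n(self):
        lo = mcnemar_power(PowerSpec(790, 0.10, 0.15, 0.22))
        hi = mcnemar_power(PowerSpec(1580, 0.10, 0.15, 0.22))
        assert hi > lo

    def test_infeasible_designs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(790, 0.10, 0.30, 0.22)  # delta > discordant
        with pytest.raises(ValueError):
            PowerSpec(790, 0.10, 0.15, 0.02)  # psi <= delta^2
        with pytest.raises(ValueError):
            PowerSpec(790, 1.5, 0.15, 0.22)

    def test_simulation_agrees_with_exact_enumeration(self):
        spec = PowerSpec(790, 0.10, 0.15, 0.22, 0.05)
        exact = mcnemar_power(spec)
        sim = simulate_mcnemar_power(spec, reps=100_000, seed=4)
        assert sim == pytest.approx(exact, abs=0.01)

    def test_simulation_grid_agreement(self):
        """Enumeration and Monte Carlo are two routes to the same quantity."""
        for i, (n, rho, d, psi) in enumerate(
            [(2000, 0.1, 0.1, 0.3), (500, 0.5, 0.2, 0.4), (4000, 0.1, 0.05, 0.2)]
        ):
            spec = PowerSpec(n, rho, d, psi)
            exact = mcnemar_power(spec)
            sim = simulate_mcnemar_power(spec, reps=100_000, seed=100 + i)
            assert sim == pytest.approx(exact, abs=0.02)


class TestRunStudy:
    def test_perfect_generator_gives_perfect_or_models(self, lexicon):
        from pwudflag.flagging import build_signals
        from pwudflag.models import builtin_registry
        from pwudflag.simulate import GeneratorConfig, generate_corpus

        cfg = GeneratorConfig(
            n_encounters=40, prevalence=0.5, p_mention=1.0,
            p_negated_mention=0.0, p_false_trigger=0.0,
            icd_sensitivity=1.0, icd_specificity=1.0, seed=3,
        )
        encounters, gold, _ = generate_corpus(cfg, lexicon=lexicon)
        signals = build_signals(encounters, lexicon)
        acc, nri = run_study(signals, gold, builtin_registry())
        acc = acc.set_index("model_id")
        for mid in ["icd_only", "regex_only", "icd_or_regex", "icd_or_regex_or_context"]:
            assert acc.loc[mid, "sensitivity"] == pytest.approx(1.0)
        # baseline against itself is an all-zero NRI row
        base = nri.set_index("model_id").loc["icd_only"]
        assert base["wnri"] == base["nri_e"] == base["nri_ne"] == 0.0

    def test_or_rows_never_reclassify_events_down(self, lexicon, small_corpus):
        from pwudflag.flagging import build_signals
        from pwudflag.models import builtin_registry

        _, encounters, gold, _ = small_corpus
        signals = build_signals(encounters, lexicon)
        _, nri = run_study(signals, gold, builtin_registry())
        nri = nri.set_index("model_id")
        for mid in ["icd_or_regex", "icd_or_context", "icd_or_regex_or_context",
                    "icd_or_regex_ge10", "icd_or_regex_ge25", "icd_or_regex_ge50"]:
            assert nri.loc[mid, "nri_e"] >= 0
            assert nri.loc[mid, "nri_ne"] <= 0
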