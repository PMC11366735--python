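"""Confusion metrics, rule ordering and the sequential classifier."""

import numpy as np
import pytest

from lesiondx import params
from lesiondx.ruletree import (
    ThresholdRule,
    classify_patient,
    confusion_metrics,
    evaluate_tree,
    fit_tree,
    order_rules,
    patient_feature_table,
)
from lesiondx.schema import Cohort

from conftest import make_patient


class TestConfusionMetrics:
    def test_perfusion_rule_worked_example(self):
        # 9/17 lymphoma perfusion patients with the typical curve,
        # 0/37 glioblastoma perfusion patients
        m = confusion_metrics(tp=9, fp=0, tn=37, fn=8)
        assert m.accuracy == pytest.approx(0.85, abs=0.005)
        assert m.sensitivity == pytest.approx(0.53, abs=0.005)
        assert m.specificity == 1.0
        assert m.ppv == 1.0
        assert m.npv == pytest.approx(0.82, abs=0.005)

    def test_perfect_table(self):
        m = confusion_metrics(1, 0, 1, 0)
        assert (m.accuracy, m.sensitivity, m.specificity, m.ppv, m.npv) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_undefined_ratios_are_absent(self):
        m = confusion_metrics(0, 0, 5, 5)
        assert m.ppv is None
        assert m.npv == 0.5

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 1, 0)


def _published_rules():
    """Rules carrying the published per-rule sensitivity/specificity."""
    rules = []
    for feat, _acc, sens, spec, _ppv, _npv in params.PUBLISHED_RULE_METRICS:
        kind, modality = (
            ("boolean_flag", "perfusion") if feat == "typical_curve"
            else ("category_membership", "none")
            if feat in ("stripe_or_tree", "cystic_or_cystic_solid")
            else ("threshold", "none")
        )
        rules.append(
            ThresholdRule(
                feature=feat, kind=kind,
                direction="absent" if feat == "cystic_or_cystic_solid"
                else "present" if kind != "threshold"
                else "less_than",
                threshold=1.0 if kind == "threshold" else None,
                votes_for="mCNSL", other="mGB",
                J=sens + spec - 1.0, sensitivity=sens, specificity=spec,
                requires_modality=modality, p_value=0.001,
            )
        )
    return rules


class TestOrdering:
    def test_published_metrics_reproduce_published_row_order(self):
        rules = _published_rules()
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = [rules[i] for i in rng.permutation(len(rules))]
            got = [r.feature for r in order_rules(shuffled)]
            assert got == [row[0] for row in params.PUBLISHED_RULE_METRICS]

    def test_invariant_structure(self):
        ordered = order_rules(_published_rules())
        assert ordered[0].requires_modality == "perfusion"
        perfect = [r.specificity == 1.0 for r in ordered]
        # every perfect-specificity rule precedes every imperfect one
        assert perfect == sorted(perfect, reverse=True)
        imperfect = [r.J for r in ordered if r.specificity < 1.0]
        assert imperfect == sorted(imperfect, reverse=True)


class TestFitTree:
    def test_single_entity_rejected(self):
        cohort = Cohort([make_patient() for _ in range(10)])
        with pytest.raises(ValueError, match="both entities"):
            fit_tree(cohort)

    def test_perfectly_separating_boolean_feature(self):
        pats = [
            make_patient("mCNSL", lesion={"morphology": "stripe_or_tree"})
            for _ in range(20)
        ] + [make_patient("mGB") for _ in range(20)]
        tree = fit_tree(Cohort(pats), candidate_features=["stripe_or_tree"])
        assert len(tree.rules_) == 1
        assert tree.rules_[0].J == pytest.approx(1.0)

    def test_no_significant_rule_warns_and_returns_empty(self):
        pats = [make_patient("mCNSL") for _ in range(5)] + [
            make_patient("mGB") for _ in range(5)
        ]
        with pytest.warns(UserWarning, match="significance gate"):
            tree = fit_tree(Cohort(pats), candidate_features=["diameter_mm"])
        assert tree.rules_ == []

    def test_synthetic_cohort_rule_directions(self, synthetic_cohort):
        tree = fit_tree(synthetic_cohort)
        by_feature = {r.feature: r for r in tree.rules_}
        # published directions: small/dark lesions for lymphoma, bright edema
        assert by_feature["adc_ratio_tumor"].direction == "less_than"
        assert by_feature["diameter_mm"].direction == "less_than"
        assert by_feature["adc_ratio_edema_5mm"].direction == "greater_than"
        assert by_feature["typical_curve"].direction == "present"
        assert by_feature["cystic_or_cystic_solid"].direction == "absent"
        assert tree.rules_[0].feature == "typical_curve"

    def test_injected_thresholds_bypass_fitting(self, synthetic_cohort):
        injected = {
            "adc_ratio_tumor": ("less_than", 0.87),
            "adc_ratio_edema_5mm": ("greater_than", 1.88),
            "diameter_mm": ("less_than", 20.0),
        }
        tree = fit_tree(synthetic_cohort, injected_thresholds=injected)
        by_feature = {r.feature: r for r in tree.rules_}
        for feat, (direction, value) in injected.items():
            assert by_feature[feat].direction == direction
            assert by_feature[feat].threshold == value


@pytest.fixture(scope="module")
def tree(synthetic_cohort):
    return fit_tree(synthetic_cohort)


class TestClassify:
    def test_typical_curve_fires_first(self, tree):
        pat = make_patient(
            "mCNSL",
            perfusion_available=True,
            lesion={"typical_curve": True, "rcbv_increased": True},
        )
        pred, trace = classify_patient(pat, tree)
        assert pred == "mCNSL"
        assert len(trace) == 1
        assert trace[0]["feature"] == "typical_curve"

    def test_cystic_patient_without_perfusion_is_glioblastoma(self, tree):
        pat = make_patient("mGB", lesion={"morphology": "cystic"})
        pred, trace = classify_patient(pat, tree)
        assert pred == "mGB"
        fired = [s for s in trace if s["outcome"].startswith("fired")]
        assert fired[0]["feature"] == "cystic_or_cystic_solid"
        assert any("skipped: modality unavailable" in s["outcome"] for s in trace)

    def test_unmeasurable_patient_abstains(self, synthetic_cohort):
        tree = fit_tree(synthetic_cohort, candidate_features=["typical_curve"])
        pat = make_patient("mGB")  # no perfusion
        pred, trace = classify_patient(pat, tree)
        assert pred is None
        assert all("skipped" in s["outcome"] for s in trace)

    def test_first_hit_ignores_later_rules(self, tree):
        pat = make_patient(
            "mCNSL",
            perfusion_available=True,
            lesion={"typical_curve": True, "rcbv_increased": False},
        )
        truncated = fit_tree(
            Cohort([make_patient("mCNSL", perfusion_available=True,
                                 lesion={"typical_curve": True,
                                         "rcbv_increased": False})
                    for _ in range(10)]
                   + [make_patient("mGB", perfusion_available=True,
                                   lesion={"typical_curve": False,
                                           "rcbv_increased": False})
                      for _ in range(10)]),
            candidate_features=["typical_curve"],
        )
        assert classify_patient(pat, tree)[0] == classify_patient(pat, truncated)[0]


class TestEvaluate:
    def test_fixture_perfusion_rule_reproduces_published_row(self, fixture_cohort):
        tree = fit_tree(
            fixture_cohort,
            candidate_features=["typical_curve", "stripe_or_tree"],
        )
        report = evaluate_tree(tree, fixture_cohort, unit="patient")
        m = report.per_rule["typical_curve"]
        assert (m.tp, m.fp, m.tn, m.fn) == (9, 0, 37, 8)
        assert m.accuracy == pytest.approx(0.85, abs=0.005)
        assert m.npv == pytest.approx(0.82, abs=0.005)

    def test_stored_rule_metrics_match_reevaluation(self, synthetic_cohort):
        tree = fit_tree(synthetic_cohort)
        report = evaluate_tree(tree, synthetic_cohort, unit="patient")
        for rule in tree.rules_:
            m = report.per_rule[rule.feature]
            assert m.sensitivity == pytest.approx(rule.sensitivity, abs=1e-12)
            assert m.specificity == pytest.approx(rule.specificity, abs=1e-12)

    def test_perfect_feature_gives_perfect_accuracy_both_aggregations(self):
        pats = [
            make_patient("mCNSL", lesion={"morphology": "stripe_or_tree"})
            for _ in range(15)
        ] + [make_patient("mGB") for _ in range(15)]
        for aggregation in ("first_hit", "weighted_vote"):
            tree = fit_tree(Cohort(pats), candidate_features=["stripe_or_tree"],
                            aggregation=aggregation, default_policy="majority")
            report = evaluate_tree(tree, Cohort(pats))
            assert report.overall.accuracy == 1.0

    def test_stripe_rule_specificity_on_synthetic_cohort(self, large_synthetic_pair):
        gb, ly = large_synthetic_pair
        cohort = Cohort(gb.patients + ly.patients)
        tree = fit_tree(cohort, candidate_features=["stripe_or_tree"])
        report = evaluate_tree(tree, cohort, unit="lesion")
        assert report.per_rule["stripe_or_tree"].specificity == pytest.approx(
            1.0, abs=0.005
        )

    def test_abstentions_counted(self, synthetic_cohort):
        tree = fit_tree(synthetic_cohort, candidate_features=["typical_curve"])
        report = evaluate_tree(tree, synthetic_cohort)
        X = patient_feature_table(synthetic_cohort)
        no_perf = int((~X["perfusion_available"]).sum())
        no_curve = int(
            (X["perfusion_available"] & (X["typical_curve"] == 0.0)).sum()
        )
        # one-sided rule: patients without perfusion or without the marker
        # cannot be classified
        assert report.abstentions == no_perf + no_curve
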