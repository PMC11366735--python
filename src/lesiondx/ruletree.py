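"""The sequential rule-list diagnostic classifier.

The published interpretation algorithm is an ordered list of single-feature
rules: the MR-perfusion rule always comes first, then every rule with
perfect specificity for the positive entity, then the remaining
significantly different features in descending order of Youden's J.  Rules
whose modality (perfusion, SWI) was not acquired for a patient are skipped.

Two kinds of rule semantics arise from the flowchart reading:

* one-sided rules (a marker *present* votes for the positive class and its
  absence is uninformative) - the perfusion typical-curve and the
  stripe/tree-enhancement rules;
* two-sided rules (the rule always splits: condition true votes positive,
  false votes negative) - threshold rules on patient-mean features and the
  "no cystic or cystic-solid lesion" morphology rule.

``RuleListClassifier`` is a scikit-learn-style estimator over a
patient-level feature table; :func:`fit_tree` / :func:`classify_patient` /
:func:`evaluate_tree` are the cohort-facing wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .roc import POSITIVE_HIGH, POSITIVE_LOW, roc_curve, youden_optimal_threshold, _apply
from .schema import Cohort, Patient
from .stats import bonferroni_alpha, two_proportion_test, two_sided_t_test

# ---------------------------------------------------------------------------
# confusion metrics


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Accuracy/sensitivity/specificity/PPV/NPV from a 2x2 table; ratios
    with a zero denominator are reported absent (None), not zero."""
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("the 2x2 table must contain at least one record")

    def _div(num, den):
        return num / den if den > 0 else None

    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / total,
        sensitivity=_div(tp, tp + fn),
        specificity=_div(tn, tn + fp),
        ppv=_div(tp, tp + fp),
        npv=_div(tn, tn + fn),
    )


# ---------------------------------------------------------------------------
# feature registry and patient-level feature table

_CONTINUOUS = (
    "diameter_mm",
    "edema_mm",
    "nearest_lesion_distance_mm",
    "adc_ratio_tumor",
    "adc_ratio_edema_5mm",
    "adc_ratio_edema_10mm",
    "adc_ratio_edema_20mm",
    "flair_ratio_tumor",
    "flair_ratio_edema_5mm",
    "flair_ratio_edema_10mm",
    "flair_ratio_edema_20mm",
)

#: feature name -> (kind, requires_modality)
FEATURE_KINDS: dict[str, tuple[str, str]] = {
    **{f: ("threshold", "none") for f in _CONTINUOUS},
    "typical_curve": ("boolean_flag", "perfusion"),
    "rcbv_increased": ("boolean_flag", "perfusion"),
    "swi_hemorrhage": ("boolean_flag", "swi"),
    "swi_vascularization": ("boolean_flag", "swi"),
    "contrast_enhancing": ("boolean_flag", "none"),
    "flair_connected": ("boolean_flag", "none"),
    "stripe_or_tree": ("category_membership", "none"),
    "cystic_or_cystic_solid": ("category_membership", "none"),
}

#: the seven published candidate features, in no particular order
DEFAULT_CANDIDATES = (
    "typical_curve",
    "stripe_or_tree",
    "cystic_or_cystic_solid",
    "adc_ratio_edema_5mm",
    "flair_ratio_edema_5mm",
    "adc_ratio_tumor",
    "diameter_mm",
)


def _any_flag(values: Sequence[Optional[bool]]) -> Optional[float]:
    present = [v for v in values if v is not None]
    if not present:
        return np.nan
    return float(any(present))


def patient_features(patient: Patient) -> dict:
    """Patient-level reduction: means of continuous lesion features,
    any-lesion semantics for boolean/category features."""
    row: dict = {
        "entity": patient.entity,
        "subtype": patient.subtype,
        "perfusion_available": patient.perfusion_available,
        "swi_available": patient.swi_available,
    }
    for f in _CONTINUOUS:
        vals = [getattr(l, f) for l in patient.lesions if getattr(l, f) is not None]
        row[f] = float(np.mean(vals)) if vals else np.nan
    for f in ("typical_curve", "rcbv_increased", "swi_hemorrhage",
              "swi_vascularization", "contrast_enhancing", "flair_connected"):
        row[f] = _any_flag([getattr(l, f) for l in patient.lesions])
    row["stripe_or_tree"] = float(
        any(l.morphology == "stripe_or_tree" for l in patient.lesions)
    )
    row["cystic_or_cystic_solid"] = float(
        any(l.morphology in ("cystic", "cystic_solid") for l in patient.lesions)
    )
    return row


def patient_feature_table(cohort: Cohort) -> pd.DataFrame:
    """One row per patient; NaN encodes unmeasurable features."""
    return pd.DataFrame([patient_features(p) for p in cohort.patients])


def lesion_feature_table(cohort: Cohort) -> pd.DataFrame:
    """One row per lesion (lesion-level evaluation unit)."""
    rows = []
    for pat in cohort.patients:
        for les in pat.lesions:
            row = {
                "entity": pat.entity,
                "subtype": pat.subtype,
                "perfusion_available": pat.perfusion_available,
                "swi_available": pat.swi_available,
            }
            for f in _CONTINUOUS:
                v = getattr(les, f)
                row[f] = np.nan if v is None else float(v)
            for f in ("typical_curve", "rcbv_increased", "swi_hemorrhage",
                      "swi_vascularization", "contrast_enhancing",
                      "flair_connected"):
                v = getattr(les, f)
                row[f] = np.nan if v is None else float(v)
            row["stripe_or_tree"] = float(les.morphology == "stripe_or_tree")
            row["cystic_or_cystic_solid"] = float(
                les.morphology in ("cystic", "cystic_solid")
            )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rules

_SPEC_ONE = 1.0 - 1e-12


@dataclass(frozen=True)
class ThresholdRule:
    """A directed single-feature rule with a class vote.

    ``direction``: 'less_than'/'greater_than' for threshold rules (the
    condition ``value < t`` / ``value > t`` votes for ``votes_for``);
    'present'/'absent' for boolean and category rules.  A rule is one-sided
    (non-firing when its condition fails) exactly when a *present* marker
    votes for the positive class; every other rule splits both ways.
    """

    feature: str
    kind: str
    direction: str
    threshold: Optional[float]
    votes_for: str
    other: str
    J: float
    sensitivity: float
    specificity: float
    requires_modality: str
    p_value: float

    def __post_init__(self):
        if (self.threshold is not None) != (self.kind == "threshold"):
            raise ValueError("threshold present iff kind == 'threshold'")
        if abs(self.J - (self.sensitivity + self.specificity - 1.0)) > 1e-9:
            raise ValueError("J must equal sensitivity + specificity - 1")

    @property
    def one_sided(self) -> bool:
        """Pass (rather than vote for the other class) when the marker is
        absent: presence is proof (perfect specificity) while absence is
        non-diagnostic (imperfect sensitivity)."""
        return (
            self.kind != "threshold"
            and self.direction == "present"
            and self.specificity >= 1.0 - 1e-12
            and self.sensitivity < 1.0 - 1e-12
        )

    def measurable(self, row) -> bool:
        if self.requires_modality == "perfusion" and not row["perfusion_available"]:
            return False
        if self.requires_modality == "swi" and not row["swi_available"]:
            return False
        return not pd.isna(row[self.feature])

    def condition(self, row) -> bool:
        v = row[self.feature]
        if self.kind == "threshold":
            if self.direction == "less_than":
                return bool(v < self.threshold)
            return bool(v > self.threshold)
        flag = bool(v)
        return flag if self.direction == "present" else not flag

    def to_dict(self) -> dict:
        return {
            "feature": self.feature, "kind": self.kind,
            "direction": self.direction, "threshold": self.threshold,
            "votes_for": self.votes_for, "other": self.other,
            "J": self.J, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "requires_modality": self.requires_modality,
            "p_value": self.p_value,
        }


def rule_from_dict(doc: dict) -> ThresholdRule:
    return ThresholdRule(**doc)


def order_rules(rules: Sequence[ThresholdRule]) -> list[ThresholdRule]:
    """Published ordering: the perfusion rule first, then all rules with
    specificity 1.0, then the rest by descending Youden's J."""
    return sorted(
        rules,
        key=lambda r: (
            r.requires_modality != "perfusion",
            r.specificity < _SPEC_ONE,
            -r.J,
            -r.sensitivity,
            r.feature,
        ),
    )


# ---------------------------------------------------------------------------
# the estimator


class RuleListClassifier(BaseEstimator, ClassifierMixin):
    """Ordered-rule-list classifier over a patient-level feature table.

    Parameters
    ----------
    candidates : sequence of feature names, default the seven published ones
    positive_class : entity label the threshold directions detect
    alpha : per-rule significance gate (Welch t for continuous, Fisher for
        categorical); default Bonferroni 0.05/20
    aggregation : 'first_hit' (flowchart semantics) or 'weighted_vote'
        (J-weighted sum of all applicable rules)
    default_policy : 'abstain' or 'majority' when no rule applies
    injected_thresholds : mapping feature -> (direction, value) bypassing
        Youden fitting, for reproduction runs with pre-registered cut-offs
    """

    def __init__(
        self,
        candidates=None,
        positive_class: str = "mCNSL",
        alpha: float = bonferroni_alpha(0.05, 20),
        aggregation: str = "first_hit",
        default_policy: str = "abstain",
        t_variant: str = "welch",
        injected_thresholds=None,
    ):
        self.candidates = candidates
        self.positive_class = positive_class
        self.alpha = alpha
        self.aggregation = aggregation
        self.default_policy = default_policy
        self.t_variant = t_variant
        self.injected_thresholds = injected_thresholds

    # -- fitting -----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        if self.aggregation not in ("first_hit", "weighted_vote"):
            raise ValueError("aggregation must be 'first_hit' or 'weighted_vote'")
        if self.default_policy not in ("abstain", "majority"):
            raise ValueError("default_policy must be 'abstain' or 'majority'")
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("exactly two classes required")
        if self.positive_class not in classes:
            raise ValueError(
                f"positive_class {self.positive_class!r} absent from y"
            )
        self.classes_ = classes
        pos = self.positive_class
        neg = [c for c in classes if c != pos][0]
        self.negative_class_ = neg
        self.majority_class_ = classes[np.argmax([(y == c).sum() for c in classes])]

        injected = dict(self.injected_thresholds or {})
        rules = []
        for feat in self.candidates or DEFAULT_CANDIDATES:
            if feat not in FEATURE_KINDS:
                raise ValueError(f"unknown candidate feature {feat!r}")
            kind, modality = FEATURE_KINDS[feat]
            values = X[feat].to_numpy(dtype=float)
            ok = ~np.isnan(values)
            if ok.sum() == 0:
                continue
            v, lab = values[ok], (y[ok] == pos)
            if lab.all() or not lab.any():
                continue
            if kind == "threshold":
                rule = self._fit_threshold_rule(
                    feat, modality, v, lab, injected.get(feat), pos, neg
                )
            else:
                rule = self._fit_boolean_rule(feat, kind, modality, v, lab, pos, neg)
            if rule is None:
                continue
            # pre-registered (injected) rules are kept regardless of the
            # in-sample significance gate
            if feat in injected or rule.p_value <= self.alpha:
                rules.append(rule)
        if not rules:
            warnings.warn(
                "no candidate feature passed the significance gate; "
                "the rule list is empty",
                stacklevel=2,
            )
        self.rules_ = order_rules(rules)
        return self

    def _fit_threshold_rule(self, feat, modality, v, lab, injected, pos, neg):
        a, b = v[lab], v[~lab]
        if len(a) < 2 or len(b) < 2:
            return None
        p = two_sided_t_test(a, b, variant=self.t_variant).p_value
        if injected is not None:
            direction, cut = injected
            if direction not in ("less_than", "greater_than"):
                raise ValueError(f"bad injected direction {direction!r}")
            roc_dir = POSITIVE_LOW if direction == "less_than" else POSITIVE_HIGH
            sens = float(_apply(a, cut, roc_dir).mean())
            spec = float(1.0 - _apply(b, cut, roc_dir).mean())
        else:
            choice = youden_optimal_threshold(roc_curve(v, lab))
            direction = (
                "less_than" if choice.direction == POSITIVE_LOW else "greater_than"
            )
            cut, sens, spec = choice.threshold, choice.sensitivity, choice.specificity
        return ThresholdRule(
            feature=feat, kind="threshold", direction=direction,
            threshold=float(cut), votes_for=pos, other=neg,
            J=sens + spec - 1.0, sensitivity=sens, specificity=spec,
            requires_modality=modality, p_value=p,
        )

    def _fit_boolean_rule(self, feat, kind, modality, v, lab, pos, neg):
        flags = v.astype(bool)
        k1, n1 = int(flags[lab].sum()), int(lab.sum())
        k2, n2 = int(flags[~lab].sum()), int((~lab).sum())
        p = two_proportion_test(k1, n1, k2, n2).p_value
        direction = "present" if k1 / n1 >= k2 / n2 else "absent"
        if direction == "present":
            sens, spec = k1 / n1, 1.0 - k2 / n2
        else:
            sens, spec = 1.0 - k1 / n1, k2 / n2
        return ThresholdRule(
            feature=feat, kind=kind, direction=direction, threshold=None,
            votes_for=pos, other=neg, J=sens + spec - 1.0,
            sensitivity=sens, specificity=spec,
            requires_modality=modality, p_value=p,
        )

    # -- prediction --------------------------------------------------------

    def decision_trace(self, row) -> tuple[Optional[str], list[dict]]:
        """Classify one feature-table row; return (prediction, trace).

        The trace lists every rule consulted with its outcome; a ``None``
        prediction is an abstention under the 'abstain' policy.
        """
        trace: list[dict] = []
        if self.aggregation == "first_hit":
            for rule in self.rules_:
                if not rule.measurable(row):
                    trace.append(
                        {"feature": rule.feature,
                         "outcome": "skipped: modality unavailable"}
                    )
                    continue
                if rule.condition(row):
                    trace.append(
                        {"feature": rule.feature, "outcome": f"fired: {rule.votes_for}"}
                    )
                    return rule.votes_for, trace
                if rule.one_sided:
                    trace.append(
                        {"feature": rule.feature, "outcome": "not present: pass"}
                    )
                    continue
                trace.append(
                    {"feature": rule.feature, "outcome": f"fired: {rule.other}"}
                )
                return rule.other, trace
            return self._default(), trace
        # weighted_vote
        score = 0.0
        any_applicable = False
        for rule in self.rules_:
            if not rule.measurable(row):
                trace.append(
                    {"feature": rule.feature,
                     "outcome": "skipped: modality unavailable"}
                )
                continue
            any_applicable = True
            if rule.condition(row):
                score += rule.J
                trace.append(
                    {"feature": rule.feature,
                     "outcome": f"vote {rule.votes_for} (+{rule.J:.3f})"}
                )
            elif rule.one_sided:
                trace.append({"feature": rule.feature, "outcome": "not present: pass"})
            else:
                score -= rule.J
                trace.append(
                    {"feature": rule.feature,
                     "outcome": f"vote {rule.other} (-{rule.J:.3f})"}
                )
        if not any_applicable or score == 0.0:
            return self._default(), trace
        return (self.positive_class if score > 0 else self.negative_class_), trace

    def _default(self) -> Optional[str]:
        if self.default_policy == "majority":
            return self.majority_class_
        return None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        out = [self.decision_trace(row)[0] for _, row in X.iterrows()]
        return np.asarray(out, dtype=object)

    def _check_fitted(self):
        if not hasattr(self, "rules_"):
            raise RuntimeError("classifier is not fitted")


# ---------------------------------------------------------------------------
# cohort-facing wrappers


def fit_tree(
    cohort: Cohort,
    candidate_features=None,
    positive_entity: str = "mCNSL",
    alpha: float = bonferroni_alpha(0.05, 20),
    aggregation: str = "first_hit",
    default_policy: str = "abstain",
    injected_thresholds=None,
) -> RuleListClassifier:
    """Fit the ordered diagnostic rule list on a labeled cohort."""
    X = patient_feature_table(cohort)
    entities = set(X["entity"])
    if len(entities) < 2:
        raise ValueError("cohort must contain both entities")
    clf = RuleListClassifier(
        candidates=candidate_features,
        positive_class=positive_entity,
        alpha=alpha,
        aggregation=aggregation,
        default_policy=default_policy,
        injected_thresholds=injected_thresholds,
    )
    return clf.fit(X, X["entity"].to_numpy())


def classify_patient(patient: Patient, tree: RuleListClassifier):
    """Apply a fitted rule list to one patient; returns
    (predicted entity or None, rule trace)."""
    tree._check_fitted()
    if not tree.rules_:
        return tree._default(), []
    row = pd.Series(patient_features(patient))
    return tree.decision_trace(row)


@dataclass(frozen=True)
class EvaluationReport:
    per_rule: dict  # feature -> ConfusionMetrics (rule as standalone test)
    overall: Optional[ConfusionMetrics]
    abstentions: int
    n_records: int
    unit: str


def evaluate_tree(
    tree: RuleListClassifier, cohort: Cohort, unit: str = "patient"
) -> EvaluationReport:
    """Score a fitted rule list on a labeled cohort.

    Per-rule metrics treat each rule as a standalone two-sided test over
    the records where its modality is available and its feature measurable
    (the published per-rule table convention); overall metrics come from
    the sequential classifier over non-abstaining records.
    """
    if unit == "patient":
        X = patient_feature_table(cohort)
    elif unit == "lesion":
        X = lesion_feature_table(cohort)
    else:
        raise ValueError("unit must be 'patient' or 'lesion'")
    y = X["entity"].to_numpy()
    pos = tree.positive_class

    per_rule = {}
    for rule in tree.rules_:
        tp = fp = tn = fn = 0
        for idx, row in X.iterrows():
            if not rule.measurable(row):
                continue
            predicted_pos = rule.condition(row)
            actual_pos = y[idx] == pos
            tp += predicted_pos and actual_pos
            fp += predicted_pos and not actual_pos
            fn += (not predicted_pos) and actual_pos
            tn += (not predicted_pos) and not actual_pos
        if tp + fp + tn + fn:
            per_rule[rule.feature] = confusion_metrics(tp, fp, tn, fn)

    tp = fp = tn = fn = abstain = 0
    for idx, row in X.iterrows():
        pred, _ = tree.decision_trace(row) if tree.rules_ else (None, [])
        if pred is None:
            abstain += 1
            continue
        actual_pos = y[idx] == pos
        predicted_pos = pred == pos
        tp += predicted_pos and actual_pos
        fp += predicted_pos and not actual_pos
        fn += (not predicted_pos) and actual_pos
        tn += (not predicted_pos) and not actual_pos
    overall = confusion_metrics(tp, fp, tn, fn) if tp + fp + tn + fn else None
    return EvaluationReport(
        per_rule=per_rule,
        overall=overall,
        abstentions=abstain,
        n_records=len(X),
        unit=unit,
    )
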