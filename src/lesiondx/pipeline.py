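"""End-to-end pipeline: generate -> summarize -> compare -> roc -> fit ->
evaluate, with every artifact written as plain text and fully determined by
the configuration and seed."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import write_cohort_table
from .roc import roc_curve, youden_optimal_threshold
from .ruletree import (
    DEFAULT_CANDIDATES,
    FEATURE_KINDS,
    RuleListClassifier,
    evaluate_tree,
    fit_tree,
    patient_feature_table,
    rule_from_dict,
)
from .schema import Cohort, validate_cohort
from .simulate import default_config, sample_cohort
from .stats import (
    bonferroni_alpha,
    summary_frame,
    group_summary,
    two_proportion_test,
    two_sided_t_test,
)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_patients: dict = field(default_factory=lambda: {"mGB": 50, "mCNSL": 50})
    alpha_family: float = 0.05
    m_comparisons: int = 20
    aggregation: str = "first_hit"
    unit: str = "patient"
    injected_thresholds: dict | None = None
    out_dir: str = "lesiondx_run"

    def validate(self) -> None:
        for entity, n in self.n_patients.items():
            if n <= 0:
                raise ValueError(f"n_patients[{entity!r}] must be positive")
        if not 0 < self.alpha_family < 1:
            raise ValueError("alpha_family must be in (0, 1)")
        if self.injected_thresholds:
            for feat in self.injected_thresholds:
                if feat not in FEATURE_KINDS:
                    raise ValueError(f"unknown injected feature {feat!r}")


def compare_entities(cohort: Cohort) -> pd.DataFrame:
    """Lesion-level entity comparison: Welch t for continuous features,
    Fisher's exact test for category/flag frequencies."""
    summaries = group_summary(cohort, "entity")
    if set(summaries) != {"mGB", "mCNSL"}:
        raise ValueError("cohort must contain both entities")
    a, b = summaries["mGB"], summaries["mCNSL"]
    rows = []
    gb_lesions = cohort.subset("mGB").lesions
    ly_lesions = cohort.subset("mCNSL").lesions
    for feat in a.features:
        if feat not in b.features or feat == "lesions_per_patient":
            continue
        va = [getattr(l, feat) for l in gb_lesions if getattr(l, feat) is not None]
        vb = [getattr(l, feat) for l in ly_lesions if getattr(l, feat) is not None]
        res = two_sided_t_test(va, vb)
        rows.append(
            {"feature": feat, "test": res.test_name, "statistic": res.statistic,
             "p_value": res.p_value, "n_mGB": res.n1, "n_mCNSL": res.n2}
        )
    for cat in a.categories:
        if cat not in b.categories:
            continue
        ca, cb = a.categories[cat], b.categories[cat]
        if ca.denominator == 0 or cb.denominator == 0:
            continue
        res = two_proportion_test(ca.count, ca.denominator, cb.count, cb.denominator)
        rows.append(
            {"feature": cat, "test": res.test_name, "statistic": res.statistic,
             "p_value": res.p_value, "n_mGB": res.n1, "n_mCNSL": res.n2}
        )
    return pd.DataFrame(rows)


def tree_to_dict(tree: RuleListClassifier) -> dict:
    return {
        "positive_class": tree.positive_class,
        "negative_class": tree.negative_class_,
        "majority_class": str(tree.majority_class_),
        "aggregation": tree.aggregation,
        "default_policy": tree.default_policy,
        "alpha": tree.alpha,
        "rules": [r.to_dict() for r in tree.rules_],
    }


def tree_from_dict(doc: dict) -> RuleListClassifier:
    clf = RuleListClassifier(
        positive_class=doc["positive_class"],
        alpha=doc["alpha"],
        aggregation=doc["aggregation"],
        default_policy=doc["default_policy"],
    )
    clf.rules_ = [rule_from_dict(r) for r in doc["rules"]]
    clf.negative_class_ = doc["negative_class"]
    clf.majority_class_ = doc["majority_class"]
    clf.classes_ = np.array(sorted([doc["positive_class"], doc["negative_class"]]))
    return clf


def evaluation_frame(report) -> pd.DataFrame:
    rows = []
    for feat, m in report.per_rule.items():
        rows.append(
            {"rule": feat, "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
             "accuracy": m.accuracy, "sensitivity": m.sensitivity,
             "specificity": m.specificity, "ppv": m.ppv, "npv": m.npv}
        )
    if report.overall is not None:
        m = report.overall
        rows.append(
            {"rule": "(overall)", "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
             "accuracy": m.accuracy, "sensitivity": m.sensitivity,
             "specificity": m.specificity, "ppv": m.ppv, "npv": m.npv}
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a run report naming the written artifacts.

    Identical config and seed produce byte-identical outputs.  A stage
    failure is reported with the stage name; artifacts written by earlier
    stages are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"seed": config.seed, "artifacts": {}, "stages": []}
    log_lines = [
        f"lesiondx {__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed {config.seed}",
    ]

    stage = "generate"
    try:
        patients = []
        for i, (entity, n) in enumerate(sorted(config.n_patients.items())):
            cfg = default_config(entity, n_patients=n, seed=config.seed + i)
            patients.extend(sample_cohort(cfg).patients)
        cohort = Cohort(patients, provenance=f"synthetic seed {config.seed}")
        violations = validate_cohort(cohort)
        if violations:
            raise ValueError(f"generated cohort invalid: {violations[:3]}")
        path = out / "cohort.csv"
        with open(path, "w") as fh:
            write_cohort_table(cohort, fh, "csv")
        report["artifacts"]["cohort"] = str(path)
        report["stages"].append(stage)

        stage = "summarize"
        sframe = summary_frame(group_summary(cohort, "entity"))
        path = out / "summary_by_entity.csv"
        sframe.to_csv(path, index=False)
        report["artifacts"]["summary"] = str(path)
        report["stages"].append(stage)

        stage = "compare"
        cframe = compare_entities(cohort)
        path = out / "comparison.csv"
        cframe.to_csv(path, index=False)
        report["artifacts"]["comparison"] = str(path)
        report["stages"].append(stage)

        stage = "roc"
        X = patient_feature_table(cohort)
        labels = (X["entity"] == "mCNSL").to_numpy()
        roc_doc = {}
        for feat in DEFAULT_CANDIDATES:
            if FEATURE_KINDS[feat][0] != "threshold":
                continue
            vals = X[feat].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            roc = roc_curve(vals[ok], labels[ok])
            choice = youden_optimal_threshold(roc)
            roc_doc[feat] = {
                "auc": roc.auc, "direction": roc.direction,
                "threshold": choice.threshold, "J": choice.J,
                "sensitivity": choice.sensitivity,
                "specificity": choice.specificity,
            }
        path = out / "roc.json"
        path.write_text(json.dumps(roc_doc, indent=1) + "\n")
        report["artifacts"]["roc"] = str(path)
        report["stages"].append(stage)

        stage = "fit"
        alpha = bonferroni_alpha(config.alpha_family, config.m_comparisons)
        tree = fit_tree(
            cohort,
            alpha=alpha,
            aggregation=config.aggregation,
            injected_thresholds=config.injected_thresholds,
        )
        path = out / "tree.json"
        path.write_text(json.dumps(tree_to_dict(tree), indent=1) + "\n")
        report["artifacts"]["tree"] = str(path)
        report["stages"].append(stage)

        stage = "evaluate"
        ev = evaluate_tree(tree, cohort, unit=config.unit)
        path = out / "evaluation.csv"
        evaluation_frame(ev).to_csv(path, index=False)
        report["artifacts"]["evaluation"] = str(path)
        report["stages"].append(stage)
        log_lines.append(f"abstentions: {ev.abstentions}/{ev.n_records}")
    except Exception as exc:
        report["error"] = f"stage {stage!r} failed: {exc}"
        log_lines.append(report["error"])

    log_lines.append("stages completed: " + ", ".join(report["stages"]))
    log_path = out / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    report["artifacts"]["log"] = str(log_path)
    if "error" in report:
        raise RuntimeError(report["error"])
    return report
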