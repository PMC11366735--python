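"""Headline reproduction computations.

Each function regenerates its inputs from the published summary parameters
and recomputes one headline quantity of the analysis: synthetic-cohort
parameter recovery (means of the tumor ADC ratio, lesion diameter and
lesions per patient), the lesion-level discrimination AUCs on Gaussian
surrogate cohorts, the headline between-entity t-test, and the
worked-example perfusion-rule metrics from the published patient counts.
All randomness derives from an integer ``seed``.
"""

from __future__ import annotations

import numpy as np

from . import params
from .roc import POSITIVE_LOW, auc, roc_curve
from .ruletree import confusion_metrics
from .simulate import default_config, sample_cohort
from .stats import bonferroni_alpha, two_sided_t_test

#: problem sizes: large enough for the stochastic tolerances, small enough
#: to run in seconds
N_PATIENTS_RECOVERY = 5000
N_GAUSSIAN = 100_000
N_REPLICATES = 100


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), stream])


def recovered_mean(
    entity: str, feature: str, seed: int, n_patients: int = N_PATIENTS_RECOVERY
):
    """Sample a cohort with the default configuration for ``entity`` and
    return (lesion-level sample mean of ``feature``, number of lesions)."""
    cfg = default_config(entity, n_patients=n_patients, seed=seed % (2**31))
    cohort = sample_cohort(cfg)
    if feature == "lesions_per_patient":
        counts = [len(p.lesions) for p in cohort.patients]
        return float(np.mean(counts)), len(counts)
    vals = [getattr(l, feature) for l in cohort.lesions]
    return float(np.mean(vals)), len(vals)


def gaussian_auc(feature: str, seed: int, n: int = N_GAUSSIAN):
    """Empirical lesion-level AUC for separating the entities by
    ``feature``, with both groups drawn from Gaussian laws at the published
    means/SDs and the positive class (mCNSL) at the low end of the scale."""
    stream = {"adc_ratio_tumor": 1, "diameter_mm": 2}[feature]
    rng = _rng(seed, stream)
    m_pos, s_pos = params.CONTINUOUS_LAWS["mCNSL"][feature][:2]
    m_neg, s_neg = params.CONTINUOUS_LAWS["mGB"][feature][:2]
    pos = rng.normal(m_pos, s_pos, n)
    neg = rng.normal(m_neg, s_neg, n)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
    return auc(roc_curve(scores, labels, direction=POSITIVE_LOW)), 2 * n


def headline_ttest_pvalues(seed: int, replicates: int = N_REPLICATES) -> np.ndarray:
    """p-values of the two-sided Welch t-test on tumor ADC ratios drawn at
    the published group sizes, means and SDs, over seeded replicates."""
    ps = np.empty(replicates)
    for r in range(replicates):
        rng = _rng(seed, 100 + r)
        m_gb, s_gb = params.CONTINUOUS_LAWS["mGB"]["adc_ratio_tumor"][:2]
        m_ly, s_ly = params.CONTINUOUS_LAWS["mCNSL"]["adc_ratio_tumor"][:2]
        a = rng.normal(m_gb, s_gb, params.N_LESIONS["mGB"])
        b = rng.normal(m_ly, s_ly, params.N_LESIONS["mCNSL"])
        ps[r] = two_sided_t_test(a, b).p_value
    return ps


def perfusion_rule_worked_example():
    """Confusion metrics of the perfusion typical-curve rule from the
    published patient counts: 9 of 17 lymphoma perfusion patients with the
    typical curve, 0 of 37 glioblastoma perfusion patients."""
    tc_pos = params.BINARY_COUNTS["mCNSL"]["typical_curve_patients"]
    tc_neg = params.BINARY_COUNTS["mGB"]["typical_curve_patients"]
    tp, n_pos = tc_pos
    fp, n_neg = tc_neg
    return confusion_metrics(tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)


def headline_quantities(seed: int) -> dict:
    """All headline reproduction quantities as {name: {value, n}}."""
    adc_mean, n_adc = recovered_mean("mCNSL", "adc_ratio_tumor", seed)
    diam_mean, n_diam = recovered_mean("mGB", "diameter_mm", seed)
    lpp, n_pat = recovered_mean("mCNSL", "lesions_per_patient", seed)
    auc_adc, n_auc = gaussian_auc("adc_ratio_tumor", seed)
    auc_diam, _ = gaussian_auc("diameter_mm", seed)
    ps = headline_ttest_pvalues(seed)
    wm = perfusion_rule_worked_example()
    return {
        "mean_adc_ratio_tumor_mcnsl": {"value": adc_mean, "n": n_adc},
        "mean_diameter_mm_mgb": {"value": diam_mean, "n": n_diam},
        "mean_lesions_per_patient_mcnsl": {"value": lpp, "n": n_pat},
        "auc_adc_ratio_tumor": {"value": auc_adc, "n": n_auc},
        "auc_diameter_mm": {"value": auc_diam, "n": n_auc},
        "ttest_p_median": {
            "value": float(np.median(ps)),
            "n": len(ps),
        },
        "ttest_frac_below_0.001": {
            "value": float((ps < 1e-3).mean()),
            "n": len(ps),
        },
        "perfusion_rule_accuracy": {"value": wm.accuracy, "n": wm.tp + wm.fp + wm.tn + wm.fn},
        "perfusion_rule_npv": {"value": wm.npv, "n": wm.tn + wm.fn},
        "bonferroni_alpha_20": {"value": bonferroni_alpha(0.05, 20), "n": 20},
    }
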