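"""Published cohort summary statistics used as calibration targets.

Two retrospective cohorts of 50 patients each: glioblastoma with multiple
foci (mGB, 181 lesions) and multifocal CNS lymphoma (mCNSL, 187 lesions).
Continuous features are given as (mean, sd, lower, upper); ratio features
have no published range, so the lower bound is 0 (ratios are positive) and
the upper bound is mean + 12 sd, far enough out to be inert.  Categorical
features are given as (count, denominator) pairs.
"""

from __future__ import annotations

N_PATIENTS = {"mGB": 50, "mCNSL": 50}
N_LESIONS = {"mGB": 181, "mCNSL": 187}


def _ratio_law(mean: float, sd: float) -> tuple[float, float, float, float]:
    return (mean, sd, 0.0, mean + 12.0 * sd)


#: (mean, sd, lower, upper) per entity
CONTINUOUS_LAWS = {
    "mGB": {
        "lesion_count": (3.6, 1.5, 2, 7),
        "diameter_mm": (24.8, 16.0, 2, 83),
        "edema_mm": (6.6, 8.4, 0, 40),
        "nearest_lesion_distance_mm": (14.0, 14.4, 1, 73),
        "adc_ratio_tumor": _ratio_law(1.05, 0.35),
        "adc_ratio_edema_5mm": _ratio_law(1.79, 0.54),
        "adc_ratio_edema_10mm": _ratio_law(2.07, 0.54),
        "adc_ratio_edema_20mm": _ratio_law(2.28, 0.50),
        "flair_ratio_tumor": _ratio_law(1.56, 0.29),
        "flair_ratio_edema_5mm": _ratio_law(1.80, 0.30),
        "flair_ratio_edema_10mm": _ratio_law(1.80, 0.27),
        "flair_ratio_edema_20mm": _ratio_law(1.78, 0.27),
    },
    "mCNSL": {
        "lesion_count": (3.8, 2.4, 2, 10),
        "diameter_mm": (18.8, 14.3, 1, 64),
        "edema_mm": (6.6, 8.3, 0, 44),
        "nearest_lesion_distance_mm": (19.4, 14.7, 1, 83),
        "adc_ratio_tumor": _ratio_law(0.89, 0.36),
        "adc_ratio_edema_5mm": _ratio_law(2.10, 1.04),
        "adc_ratio_edema_10mm": _ratio_law(2.23, 0.92),
        "adc_ratio_edema_20mm": _ratio_law(2.30, 0.77),
        "flair_ratio_tumor": _ratio_law(1.71, 0.48),
        "flair_ratio_edema_5mm": _ratio_law(1.92, 0.92),
        "flair_ratio_edema_10mm": _ratio_law(2.03, 0.81),
        "flair_ratio_edema_20mm": _ratio_law(2.04, 0.69),
    },
}

#: published lesion-level medians where available (else None)
MEDIANS = {
    "mGB": {"diameter_mm": None, "edema_mm": 3.0, "nearest_lesion_distance_mm": 5.0},
    "mCNSL": {"diameter_mm": 16.0, "edema_mm": 3.0, "nearest_lesion_distance_mm": 20.0},
}

#: lesion-level morphology counts; the mCNSL rows sum to 184/187 with a
#: further "nodular adjacent to the dura" group reported in prose; the
#: remaining 3 lesions are filled as extra_axial_nodular.
MORPHOLOGY_COUNTS = {
    "mGB": {
        "solid": 25,
        "cystic_solid": 25,
        "cystic": 65,
        "cortical_infiltration": 66,
        "stripe_or_tree": 0,
        "extra_axial_nodular": 0,
    },
    "mCNSL": {
        "solid": 139,
        "cystic_solid": 3,
        "cystic": 11,
        "cortical_infiltration": 3,
        "stripe_or_tree": 28,
        "extra_axial_nodular": 3,
    },
}

#: lesion-level location counts in the published order; the mCNSL column
#: sums to 194 of 187 lesions (a bookkeeping defect of the source table),
#: so consumers renormalize (generator) or truncate (fixture).
LOCATION_COUNTS = {
    "mGB": {
        "frontal": 48, "parietal": 22, "temporal": 40, "occipital": 8,
        "diencephalon": 18, "cerebral_peduncle": 0, "brain_stem": 4,
        "cerebellum": 1, "corpus_callosum": 22, "septum_pellucidum": 2,
        "basal_ganglia": 6, "internal_capsule": 5, "insula": 4,
        "ependymal_periventricular": 1, "intraventricular": 0,
        "leptomeningeal": 0,
    },
    "mCNSL": {
        "frontal": 46, "parietal": 13, "temporal": 23, "occipital": 12,
        "diencephalon": 9, "cerebral_peduncle": 7, "brain_stem": 14,
        "cerebellum": 12, "corpus_callosum": 24, "septum_pellucidum": 4,
        "basal_ganglia": 12, "internal_capsule": 1, "insula": 0,
        "ependymal_periventricular": 14, "intraventricular": 1,
        "leptomeningeal": 2,
    },
}

#: (count, denominator); lesion-level unless noted
BINARY_COUNTS = {
    "mGB": {
        "contrast_enhancing": (139, 181),
        "flair_connected": (114, 181),
        "perfusion_available_patients": (37, 50),
        "perfusion_lesions": (134, 181),
        "rcbv_increased": (85, 134),
        "typical_curve": (0, 134),
        "typical_curve_patients": (0, 37),
        "swi_available_patients": (14, 50),
        "swi_lesions": (51, 181),
        "swi_hemorrhage": (7, 51),
        "swi_vascularization": (4, 51),
        "subtype_multifocal_patients": (38, 50),
    },
    "mCNSL": {
        "contrast_enhancing": (165, 187),
        "flair_connected": (92, 187),
        "perfusion_available_patients": (17, 50),
        "perfusion_lesions": (73, 187),
        "rcbv_increased": (40, 73),
        "typical_curve": (23, 73),
        "typical_curve_patients": (9, 17),
        "swi_available_patients": (10, 50),
        "swi_lesions": (33, 187),
        "swi_hemorrhage": (12, 33),
        "swi_vascularization": (17, 33),
        "subtype_PCNSL_patients": (38, 50),
    },
}

#: published optimal thresholds for detecting mCNSL, with AUC/sens/spec
PUBLISHED_THRESHOLDS = {
    "diameter_mm": {"direction": "less_than", "threshold": 20.0,
                    "auc": 0.62, "sensitivity": 0.64, "specificity": 0.56},
    "adc_ratio_tumor": {"direction": "less_than", "threshold": 0.87,
                        "auc": 0.63, "sensitivity": 0.59, "specificity": 0.64},
    "adc_ratio_edema_5mm": {"direction": "greater_than", "threshold": 1.88,
                            "auc": 0.68, "sensitivity": 0.62, "specificity": 0.67},
}

#: published per-rule diagnostic metrics of the decision algorithm, in the
#: published row order (accuracy, sensitivity, specificity, PPV, NPV)
PUBLISHED_RULE_METRICS = [
    ("typical_curve", 0.85, 0.53, 1.00, 1.00, 0.82),
    ("stripe_or_tree", 0.58, 0.16, 1.00, 1.00, 0.55),
    ("cystic_or_cystic_solid", 0.84, 0.86, 0.80, 0.81, 0.88),
    ("adc_ratio_edema_5mm", 0.69, 0.62, 0.76, 0.68, 0.71),
    ("flair_ratio_edema_5mm", 0.64, 0.57, 0.69, 0.58, 0.68),
    ("adc_ratio_tumor", 0.62, 0.59, 0.64, 0.51, 0.71),
    ("diameter_mm", 0.60, 0.64, 0.56, 0.58, 0.62),
]
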