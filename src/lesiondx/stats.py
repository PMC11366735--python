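"""Ratio features and the comparison statistics battery.

Group comparisons between the two entities use two-sided t-tests for
continuous features (Welch by default) and an exact two-sided Fisher test
for proportions; four-way subgroup contrasts use Tukey's HSD with the
Tukey-Kramer unequal-n standard errors; multiplicity is handled with a
Bonferroni-corrected per-test alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .schema import Cohort, MORPHOLOGIES, LOCATIONS

EDEMA_DISTANCES_MM = (5, 10, 20)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n1: int
    n2: int


def ratio(lesion_value: float, reference_value: float) -> float:
    """Signal normalized to contralateral normal-appearing white matter."""
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    return lesion_value / reference_value


def gradient_profile(
    values_at_5_10_20mm: Sequence[Optional[float]], reference: float
) -> dict[int, float]:
    """Perilesional ratios at 5/10/20 mm from the lesion margin.

    Absent distances (not measurable for small lesions or shallow edema)
    yield absent outputs; at least the 5 mm value must be present.
    """
    if reference <= 0:
        raise ValueError("reference value must be positive")
    vals = list(values_at_5_10_20mm)
    if len(vals) > 3:
        raise ValueError("at most three distances (5, 10, 20 mm)")
    vals += [None] * (3 - len(vals))
    if all(v is None for v in vals):
        raise ValueError("at least one distance must be present")
    if vals[0] is None:
        raise ValueError("the 5 mm value is required")
    return {
        d: v / reference
        for d, v in zip(EDEMA_DISTANCES_MM, vals)
        if v is not None
    }


def two_sided_t_test(
    group_a: Sequence[float], group_b: Sequence[float], variant: str = "welch"
) -> TestResult:
    """Two-sided two-sample t-test; ``variant`` 'welch' or 'student'.

    The statistic's sign equals sign(mean_a - mean_b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        # degenerate equal constants: no evidence of a difference
        return TestResult(0.0, 1.0, f"t-{variant}", len(a), len(b))
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return TestResult(
        float(res.statistic), float(res.pvalue), f"t-{variant}", len(a), len(b)
    )


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Exact two-sided test of two proportions (Fisher's exact test on the
    2x2 table), suitable for the small modality denominators."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n, n > 0")
    odds, p = sps.fisher_exact(
        [[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided"
    )
    return TestResult(float(odds), float(p), "fisher-exact", n1, n2)


def tukey_hsd(groups: dict[str, Sequence[float]]) -> dict[tuple[str, str], TestResult]:
    """Tukey HSD over >=3 labeled groups; one studentized-range adjusted p
    per unordered pair (Tukey-Kramer standard errors for unequal n)."""
    if len(groups) < 3:
        raise ValueError("Tukey's test needs at least three groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    res = sps.tukey_hsd(*arrays)
    out: dict[tuple[str, str], TestResult] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out[(labels[i], labels[j])] = TestResult(
                float(res.statistic[i, j]),
                float(res.pvalue[i, j]),
                "tukey-hsd",
                len(arrays[i]),
                len(arrays[j]),
            )
    return out


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test significance level for a family of ``m`` comparisons."""
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive count")
    return family_alpha / m


# ---------------------------------------------------------------------------
# cohort summaries

_CONTINUOUS_LESION_FIELDS = (
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

_BOOLEAN_LESION_FIELDS = (
    "contrast_enhancing",
    "flair_connected",
    "rcbv_increased",
    "typical_curve",
    "swi_hemorrhage",
    "swi_vascularization",
)


@dataclass(frozen=True)
class FeatureSummary:
    mean: float
    sd: Optional[float]  # absent for a single observation
    minimum: float
    maximum: float
    median: float
    n: int


@dataclass(frozen=True)
class CategorySummary:
    count: int
    denominator: int

    @property
    def proportion(self) -> float:
        return self.count / self.denominator


@dataclass(frozen=True)
class GroupSummary:
    stratum: str
    n_patients: int
    n_lesions: int
    features: dict  # name -> FeatureSummary
    categories: dict  # name -> CategorySummary


def group_summary(cohort: Cohort, stratify_by: str = "entity") -> dict[str, GroupSummary]:
    """Per-stratum feature summaries mirroring the published cohort tables.

    Denominators are lesion counts for lesion-level fields and patient
    counts for patient-level fields; modality-dependent flags are
    denominated by lesions with the modality available.
    """
    if stratify_by not in ("entity", "subtype"):
        raise ValueError("stratify_by must be 'entity' or 'subtype'")
    strata: dict[str, list] = {}
    for pat in cohort.patients:
        strata.setdefault(getattr(pat, stratify_by), []).append(pat)
    if not strata:
        raise ValueError("empty cohort")

    out = {}
    for name, pats in strata.items():
        lesions = [les for p in pats for les in p.lesions]
        features = {}
        features["lesions_per_patient"] = _summarize(
            [float(len(p.lesions)) for p in pats]
        )
        for f in _CONTINUOUS_LESION_FIELDS:
            vals = [getattr(l, f) for l in lesions if getattr(l, f) is not None]
            if vals:
                features[f] = _summarize(vals)
        categories = {}
        for token in MORPHOLOGIES:
            categories[f"morphology:{token}"] = CategorySummary(
                sum(l.morphology == token for l in lesions), len(lesions)
            )
        for token in LOCATIONS:
            categories[f"location:{token}"] = CategorySummary(
                sum(l.location == token for l in lesions), len(lesions)
            )
        for f in _BOOLEAN_LESION_FIELDS:
            present = [getattr(l, f) for l in lesions if getattr(l, f) is not None]
            if present:
                categories[f] = CategorySummary(sum(present), len(present))
        categories["perfusion_available"] = CategorySummary(
            sum(p.perfusion_available for p in pats), len(pats)
        )
        categories["swi_available"] = CategorySummary(
            sum(p.swi_available for p in pats), len(pats)
        )
        out[name] = GroupSummary(
            stratum=name,
            n_patients=len(pats),
            n_lesions=len(lesions),
            features=features,
            categories=categories,
        )
    return out


def _summarize(values: Sequence[float]) -> FeatureSummary:
    arr = np.asarray(values, dtype=float)
    return FeatureSummary(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else None,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        median=float(np.median(arr)),
        n=len(arr),
    )


def summary_frame(summaries: dict[str, GroupSummary]) -> pd.DataFrame:
    """Flatten group summaries into a tidy table (one row per stratum and
    feature/category)."""
    rows = []
    for stratum, s in summaries.items():
        for fname, fs in s.features.items():
            rows.append(
                {
                    "stratum": stratum, "feature": fname, "kind": "continuous",
                    "mean": fs.mean, "sd": fs.sd, "min": fs.minimum,
                    "max": fs.maximum, "median": fs.median, "n": fs.n,
                    "count": None, "denominator": None, "proportion": None,
                }
            )
        for cname, cs in s.categories.items():
            rows.append(
                {
                    "stratum": stratum, "feature": cname, "kind": "categorical",
                    "mean": None, "sd": None, "min": None, "max": None,
                    "median": None, "n": cs.denominator, "count": cs.count,
                    "denominator": cs.denominator, "proportion": cs.proportion,
                }
            )
    return pd.DataFrame(rows)
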