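"""Deterministic fixture cohort reconstructing the published count data.

The fixture reproduces, exactly, every categorical and modality count of
the source cohorts: 181 mGB lesions over 50 patients (37 with MR perfusion
covering 134 lesions, none with a lymphoma-typical perfusion curve; 14 with
SWI covering 51 lesions) and 187 mCNSL lesions over 50 patients (17 with
perfusion covering 73 lesions, of whom 9 patients / 23 lesions show the
typical curve; 10 with SWI covering 33 lesions).  Morphology rows are the
published ones; for mCNSL the five main rows sum to 184 of 187 and the
remaining 3 lesions are tagged ``extra_axial_nodular`` (the prose reports 6
dural-nodular lesions overlapping the solid class — an unreconciled
bookkeeping defect of the source; the row counts are kept authoritative).
The published mCNSL location column sums to 194, so locations are assigned
in the published order and truncated at 187.

Continuous fields are filled with the published group median where one is
printed, else the group mean, so the fixture supports count-based tests
only; distributional tests use the synthetic generator instead.
"""

from __future__ import annotations

from . import params
from .schema import Cohort, Lesion, Patient


def _spread(counts_by_token: dict[str, int], total: int) -> list[str]:
    """Token per lesion in vocabulary order, truncated/padded to ``total``."""
    seq: list[str] = []
    for token, count in counts_by_token.items():
        seq.extend([token] * count)
    if len(seq) < total:
        raise ValueError("counts fall short of the lesion total")
    return seq[:total]


_PATIENT_PLAN = {
    # (lesion counts of perfusion patients, of non-perfusion patients)
    "mGB": ([4] * 23 + [3] * 14, [4] * 8 + [3] * 5),
    "mCNSL": ([6] * 5 + [5] * 4 + [3] * 7 + [2], [4] * 15 + [3] * 18),
}

# patient positions (in the order produced by the plan) that carry SWI;
# chosen so the SWI lesion totals are exactly 51 (mGB) and 33 (mCNSL)
_SWI_PATIENTS = {
    "mGB": set(range(0, 9)) | set(range(23, 28)),      # 9*4 + 5*3 = 51
    "mCNSL": set(range(17, 20)) | set(range(32, 39)),  # 3*4 + 7*3 = 33
}

# lesions with the typical perfusion curve per perfusion patient (mCNSL):
# 9 of 17 patients, 23 of 73 lesions
_TYPICAL_PLAN = [3, 3, 3, 3, 3, 2, 2, 2, 2] + [0] * 8

_SUBTYPE_SPLIT = {"mGB": ("multifocal", "multicentric", 38),
                  "mCNSL": ("PCNSL", "SCNSL", 38)}


def _build_entity(entity: str) -> list[Patient]:
    perf_counts, other_counts = _PATIENT_PLAN[entity]
    lesion_counts = perf_counts + other_counts
    n_lesions = params.N_LESIONS[entity]
    assert sum(lesion_counts) == n_lesions

    laws = params.CONTINUOUS_LAWS[entity]
    fill = {
        name: params.MEDIANS[entity].get(name) or laws[name][0]
        for name in laws
        if name != "lesion_count"
    }
    morph = _spread(params.MORPHOLOGY_COUNTS[entity], n_lesions)
    loc = _spread(params.LOCATION_COUNTS[entity], n_lesions)
    bc = params.BINARY_COUNTS[entity]
    enhancing = [i < bc["contrast_enhancing"][0] for i in range(n_lesions)]
    connected = [i < bc["flair_connected"][0] for i in range(n_lesions)]

    n_perf_lesions = sum(perf_counts)
    rcbv = [i < bc["rcbv_increased"][0] for i in range(n_perf_lesions)]
    n_swi_lesions = bc["swi_hemorrhage"][1]
    hemorrhage = [i < bc["swi_hemorrhage"][0] for i in range(n_swi_lesions)]
    vascular = [i < bc["swi_vascularization"][0] for i in range(n_swi_lesions)]

    major, minor, n_major = _SUBTYPE_SPLIT[entity]
    patients: list[Patient] = []
    gi = pi = si = 0  # global / perfusion-lesion / swi-lesion cursors
    for ppos, count in enumerate(lesion_counts):
        perfusion = ppos < len(perf_counts)
        swi = ppos in _SWI_PATIENTS[entity]
        typical_quota = (
            _TYPICAL_PLAN[ppos] if entity == "mCNSL" and perfusion else 0
        )
        lesions = []
        for k in range(count):
            lesions.append(
                Lesion(
                    diameter_mm=fill["diameter_mm"],
                    morphology=morph[gi],
                    location=loc[gi],
                    edema_mm=fill["edema_mm"],
                    nearest_lesion_distance_mm=fill["nearest_lesion_distance_mm"],
                    flair_connected=connected[gi],
                    adc_ratio_tumor=fill["adc_ratio_tumor"],
                    flair_ratio_tumor=fill["flair_ratio_tumor"],
                    contrast_enhancing=enhancing[gi],
                    adc_ratio_edema_5mm=fill["adc_ratio_edema_5mm"],
                    adc_ratio_edema_10mm=fill["adc_ratio_edema_10mm"],
                    adc_ratio_edema_20mm=fill["adc_ratio_edema_20mm"],
                    flair_ratio_edema_5mm=fill["flair_ratio_edema_5mm"],
                    flair_ratio_edema_10mm=fill["flair_ratio_edema_10mm"],
                    flair_ratio_edema_20mm=fill["flair_ratio_edema_20mm"],
                    rcbv_increased=rcbv[pi] if perfusion else None,
                    typical_curve=(k < typical_quota) if perfusion else None,
                    swi_hemorrhage=hemorrhage[si] if swi else None,
                    swi_vascularization=vascular[si] if swi else None,
                )
            )
            gi += 1
            if perfusion:
                pi += 1
            if swi:
                si += 1
        patients.append(
            Patient(
                entity=entity,
                subtype=major if ppos < n_major else minor,
                lesions=lesions,
                perfusion_available=perfusion,
                swi_available=swi,
            )
        )
    return patients


def build_fixture_cohort() -> Cohort:
    """Return the deterministic two-entity fixture cohort (100 patients)."""
    return Cohort(
        _build_entity("mGB") + _build_entity("mCNSL"), provenance="fixture"
    )
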