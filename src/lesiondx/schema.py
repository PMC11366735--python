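"""Domain types for multifocal brain-lesion cohorts.

The unit of analysis is a patient presenting with 2-10 contrast-enhancing
lesions, each described by geometry (diameter, perilesional edema extent,
distance to the nearest other lesion), a morphology category, an anatomical
location, contralateral-normalized ADC and FLAIR ratios of the tumor and of
the perilesional tissue at 5/10/20 mm, and modality-dependent flags from MR
perfusion (increased rCBV; the lymphoma-typical time-signal-intensity curve
with T1 leakage and high percentage of signal recovery) and SWI (hemorrhage,
vascularization).  Modality flags are ``None`` exactly when the patient was
not scanned with that modality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

ENTITIES = ("mGB", "mCNSL")

SUBTYPES = ("multifocal", "multicentric", "PCNSL", "SCNSL", "unspecified")

#: subtype vocabulary admissible for each entity
SUBTYPES_BY_ENTITY = {
    "mGB": ("multifocal", "multicentric", "unspecified"),
    "mCNSL": ("PCNSL", "SCNSL", "unspecified"),
}

MORPHOLOGIES = (
    "solid",
    "cystic_solid",
    "cystic",
    "cortical_infiltration",
    "stripe_or_tree",
    "extra_axial_nodular",
)

LOCATIONS = (
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "diencephalon",
    "cerebral_peduncle",
    "brain_stem",
    "cerebellum",
    "corpus_callosum",
    "septum_pellucidum",
    "basal_ganglia",
    "internal_capsule",
    "insula",
    "ependymal_periventricular",
    "intraventricular",
    "leptomeningeal",
)

MIN_LESIONS = 2
MAX_LESIONS = 10


class VocabularyError(ValueError):
    """A categorical value is outside its closed vocabulary."""


@dataclass
class Lesion:
    """One tumor focus.

    ``diameter_mm`` is the mean of the three axis diameters on the
    contrast-enhanced T1 sequence.  Ratio features are lesion (or
    perilesional) signal divided by contralateral normal-appearing white
    matter; the 10 mm and 20 mm edema ratios may be ``None`` when the edema
    did not extend that far.  ``rcbv_increased`` / ``typical_curve`` are
    ``None`` without MR perfusion, ``swi_*`` flags ``None`` without SWI.
    """

    diameter_mm: float
    morphology: str
    location: str
    edema_mm: float
    nearest_lesion_distance_mm: float
    flair_connected: bool
    adc_ratio_tumor: float
    flair_ratio_tumor: float
    contrast_enhancing: bool
    adc_ratio_edema_5mm: Optional[float] = None
    adc_ratio_edema_10mm: Optional[float] = None
    adc_ratio_edema_20mm: Optional[float] = None
    flair_ratio_edema_5mm: Optional[float] = None
    flair_ratio_edema_10mm: Optional[float] = None
    flair_ratio_edema_20mm: Optional[float] = None
    rcbv_increased: Optional[bool] = None
    typical_curve: Optional[bool] = None
    swi_hemorrhage: Optional[bool] = None
    swi_vascularization: Optional[bool] = None


@dataclass
class Patient:
    entity: str
    subtype: str
    lesions: list[Lesion] = field(default_factory=list)
    perfusion_available: bool = False
    swi_available: bool = False


@dataclass
class Cohort:
    patients: list[Patient] = field(default_factory=list)
    provenance: str = "unspecified"

    def __len__(self) -> int:  # number of patients
        return len(self.patients)

    @property
    def lesions(self) -> list[Lesion]:
        return [les for pat in self.patients for les in pat.lesions]

    def subset(self, entity: str) -> "Cohort":
        return Cohort(
            [p for p in self.patients if p.entity == entity],
            provenance=f"{self.provenance}[{entity}]",
        )


_RATIO_FIELDS = (
    "adc_ratio_tumor",
    "flair_ratio_tumor",
    "adc_ratio_edema_5mm",
    "adc_ratio_edema_10mm",
    "adc_ratio_edema_20mm",
    "flair_ratio_edema_5mm",
    "flair_ratio_edema_10mm",
    "flair_ratio_edema_20mm",
)

_PERFUSION_FLAGS = ("rcbv_increased", "typical_curve")
_SWI_FLAGS = ("swi_hemorrhage", "swi_vascularization")


def _finite(x) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


def validate_cohort(cohort: Cohort) -> list[str]:
    """Check every type invariant; return a list of human-readable violations.

    An empty list means the cohort is valid.  Each violation names the
    patient index (and lesion index where applicable), the field and the
    rule that failed.  This is a reporting operation: it never raises.
    """
    report: list[str] = []
    if not cohort.patients:
        report.append("cohort: patients: non-empty cohort required")
        return report
    for i, pat in enumerate(cohort.patients):
        where = f"patient {i}"
        if pat.entity not in ENTITIES:
            report.append(f"{where}: entity: {pat.entity!r} not in {ENTITIES}")
        elif pat.subtype not in SUBTYPES_BY_ENTITY[pat.entity]:
            report.append(
                f"{where}: subtype: {pat.subtype!r} inconsistent with entity "
                f"{pat.entity}"
            )
        n = len(pat.lesions)
        if n < MIN_LESIONS:
            report.append(f"{where}: lesions: lesion count {n} < {MIN_LESIONS}")
        elif n > MAX_LESIONS:
            report.append(f"{where}: lesions: lesion count {n} > {MAX_LESIONS}")
        for j, les in enumerate(pat.lesions):
            lwhere = f"{where}, lesion {j}"
            if not (_finite(les.diameter_mm) and les.diameter_mm > 0):
                report.append(f"{lwhere}: diameter_mm: must be > 0")
            if not (_finite(les.edema_mm) and les.edema_mm >= 0):
                report.append(f"{lwhere}: edema_mm: must be >= 0")
            if not (
                _finite(les.nearest_lesion_distance_mm)
                and les.nearest_lesion_distance_mm >= 0
            ):
                report.append(
                    f"{lwhere}: nearest_lesion_distance_mm: must be >= 0"
                )
            if les.morphology not in MORPHOLOGIES:
                report.append(
                    f"{lwhere}: morphology: {les.morphology!r} not in closed "
                    "vocabulary"
                )
            if les.location not in LOCATIONS:
                report.append(
                    f"{lwhere}: location: {les.location!r} not in closed "
                    "vocabulary"
                )
            for name in _RATIO_FIELDS:
                val = getattr(les, name)
                if val is not None and not (_finite(val) and val > 0):
                    report.append(f"{lwhere}: {name}: present ratio must be > 0")
            for flags, avail, modality in (
                (_PERFUSION_FLAGS, pat.perfusion_available, "perfusion"),
                (_SWI_FLAGS, pat.swi_available, "SWI"),
            ):
                for name in flags:
                    val = getattr(les, name)
                    if val is not None and not avail:
                        report.append(
                            f"{lwhere}: {name}: set although {modality} "
                            "unavailable"
                        )
                    if val is None and avail:
                        report.append(
                            f"{lwhere}: {name}: absent although {modality} "
                            "available"
                        )
    return report
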