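import pytest

from lesiondx.fixture import build_fixture_cohort
from lesiondx.schema import Cohort, Lesion, Patient
from lesiondx.simulate import default_config, sample_cohort


def make_lesion(**overrides) -> Lesion:
    base = dict(
        diameter_mm=20.0,
        morphology="solid",
        location="frontal",
        edema_mm=5.0,
        nearest_lesion_distance_mm=10.0,
        flair_connected=True,
        adc_ratio_tumor=1.0,
        flair_ratio_tumor=1.6,
        contrast_enhancing=True,
        adc_ratio_edema_5mm=1.8,
        adc_ratio_edema_10mm=2.0,
        adc_ratio_edema_20mm=2.2,
        flair_ratio_edema_5mm=1.8,
        flair_ratio_edema_10mm=1.9,
        flair_ratio_edema_20mm=2.0,
    )
    base.update(overrides)
    return Lesion(**base)


def make_patient(entity="mGB", n_lesions=2, **overrides) -> Patient:
    subtype = "multifocal" if entity == "mGB" else "PCNSL"
    fields = dict(entity=entity, subtype=subtype,
                  perfusion_available=False, swi_available=False)
    lesion_overrides = overrides.pop("lesion", {})
    fields.update(overrides)
    return Patient(lesions=[make_lesion(**lesion_overrides) for _ in range(n_lesions)],
                   **fields)


@pytest.fixture(scope="session")
def fixture_cohort() -> Cohort:
    return build_fixture_cohort()


@pytest.fixture(scope="session")
def synthetic_cohort() -> Cohort:
    """A moderate two-entity synthetic cohort for classifier tests."""
    gb = sample_cohort(default_config("mGB", n_patients=400, seed=11))
    ly = sample_cohort(default_config("mCNSL", n_patients=400, seed=12))
    return Cohort(gb.patients + ly.patients, provenance="synthetic test")


@pytest.fixture(scope="session")
def large_synthetic_pair():
    """Larger per-entity cohorts for frequency/moment recovery checks."""
    gb = sample_cohort(default_config("mGB", n_patients=2000, seed=21))
    ly = sample_cohort(default_config("mCNSL", n_patients=2000, seed=22))
    return gb, ly
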