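import dataclasses

import pytest

from dexpbpk.config import load_compound_config, load_population_config
from dexpbpk.population import DemographicSpec, IndividualPhysiology, bsa, sample_population


@pytest.fixture(scope="session")
def pop_config():
    return load_population_config()


@pytest.fixture(scope="session")
def compound():
    return load_compound_config()


def make_subject(**overrides) -> IndividualPhysiology:
    """Hand-built subject with internally consistent BSA, for targeted tests."""
    weight = overrides.pop("weight_kg", 50.0)
    height = overrides.pop("height_cm", 150.0)
    base = dict(
        subject_id="TEST",
        age_years=10.0,
        sex="M",
        weight_kg=weight,
        height_cm=height,
        bsa_m2=bsa(weight, height),
        liver_volume_L=1.0,
        kidney_volume_L=0.2,
        blood_volume_L=3.5,
        cardiac_output_L_h=300.0,
        hepatic_blood_flow_L_h=75.0,
        renal_blood_flow_L_h=57.0,
        mppgl_mg_g=35.0,
        cyp3a4_ontogeny_fraction=1.0,
        cyp3a4_abundance_multiplier=1.0,
        gfr_ml_min=100.0,
        albumin_ratio=1.0,
        hematocrit=0.42,
    )
    base.update(overrides)
    return IndividualPhysiology(**base)


@pytest.fixture()
def subject(pop_config):
    return sample_population(DemographicSpec(2.0, 6.0, 1, seed=11), pop_config)[0]
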