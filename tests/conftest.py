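import pytest

from plantbulk import (
    ActivityParameters,
    AnthropometricProfile,
    energy_requirement,
    packaged_profile,
    packaged_references,
    scale_profile,
)

#: Median anthropometrics of the modeled bodybuilder cohort.
MEDIAN_MASS_KG = 84.5
MEDIAN_AGE_Y = 28.5


@pytest.fixture(scope="session")
def median_athlete() -> AnthropometricProfile:
    return AnthropometricProfile(
        body_mass=MEDIAN_MASS_KG,
        age=MEDIAN_AGE_Y,
        body_mass_range=(75.0, 94.0),
        age_range=(22.0, 35.0),
    )


@pytest.fixture(scope="session")
def study_activity() -> ActivityParameters:
    return ActivityParameters(pal=1.75, surplus_fraction=0.15)


@pytest.fixture(scope="session")
def vegan_profile():
    return packaged_profile()


@pytest.fixture(scope="session")
def dri_references():
    return packaged_references()


@pytest.fixture(scope="session")
def study_energy(median_athlete, study_activity):
    return energy_requirement(median_athlete, study_activity)


@pytest.fixture(scope="session")
def study_scaled(vegan_profile, study_energy):
    return scale_profile(vegan_profile, study_energy.eer)
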