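import pytest

from croppsi.coefficients import default_coefficients
from croppsi.records import CropSeasonRecord, CroppingSystem, SystemObservation
from croppsi.simulate import default_config, generate


@pytest.fixture(scope="session")
def coef():
    return default_coefficients()


@pytest.fixture(scope="session")
def small_survey():
    """A small but structurally complete synthetic survey."""
    return generate(default_config(n_within=60, n_outside=40), seed=7)


def make_record(
    season="kharif2",
    crop="aman_rice",
    household="h1",
    stratum="within_polder",
    **quantities,
) -> CropSeasonRecord:
    return CropSeasonRecord(
        household_id=household, stratum=stratum, season=season, crop=crop,
        **quantities,
    )


def make_obs(
    records, system="FFA", household="h1", stratum="within_polder"
) -> SystemObservation:
    obs = SystemObservation(
        household_id=household,
        stratum=stratum,
        system_label=CroppingSystem(system),
        records=records,
    )
    obs.validate()
    return obs


@pytest.fixture()
def toy_mfa_observation():
    """Aman (2.4 t grain, 2.0 t straw at 10% of grain price) + mungbean
    (0.9 t at triple the rice price): REY decomposes as 2.4 + 0.2 + 2.7."""
    aman = make_record(
        grain_yield=2.4, straw_yield=2.0, crop_price=20000, straw_price=2000,
    )
    mung = make_record(
        season="rabi", crop="mungbean", grain_yield=0.9, crop_price=60000,
    )
    return make_obs([mung, aman], system="MFA")
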