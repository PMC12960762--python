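import numpy as np
import pytest

from demcea import (
    BaselineParameters,
    FixtureSpec,
    StateValues,
    fixture_config,
    generate_parameter_set,
)


def make_params(
    p_death=0.0,
    p_progress=(0.0, 0.0),
    cycle_length=1.0,
    **care,
) -> BaselineParameters:
    """Hand-built parameters; ``p_death`` may be a scalar (all states) or a
    (severity, care) dict; care transitions given as e.g.
    ``mild_none_home=0.3`` (severity, from, to in {none, home, inst})."""
    care_idx = {"none": 0, "home": 1, "inst": 2}
    sev_idx = {"mild": 0, "moderate": 1, "severe": 2}
    p_care = np.zeros((3, 3, 3))
    for key, p in care.items():
        sev, c_from, c_to = key.split("_")
        p_care[sev_idx[sev], care_idx[c_from], care_idx[c_to]] = p
    pd = np.full((3, 3), p_death) if np.isscalar(p_death) else np.asarray(p_death)
    return BaselineParameters(
        p_progress=np.asarray(p_progress, dtype=float),
        p_care=p_care,
        p_death=pd.astype(float),
        cycle_length=cycle_length,
    )


def make_values(
    patient_utility=0.7,
    caregiver_utility_delta=0.0,
    formal_cost=0.0,
    informal_hours=0.0,
    unit_wage=15.0,
) -> StateValues:
    def arr(x):
        return np.full(9, x) if np.isscalar(x) else np.asarray(x, dtype=float)

    return StateValues(
        patient_utility=arr(patient_utility),
        caregiver_utility_delta=arr(caregiver_utility_delta),
        formal_cost=arr(formal_cost),
        informal_hours=arr(informal_hours),
        unit_wage=unit_wage,
    )


@pytest.fixture(scope="session")
def fx_config():
    """One exemplar full configuration shared across tests."""
    return fixture_config(FixtureSpec(seed=3))


@pytest.fixture
def random_params():
    """Factory for seeded random valid parameter sets."""

    def make(seed: int):
        return generate_parameter_set(FixtureSpec(seed=seed))

    return make
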