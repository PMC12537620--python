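import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True)
settings.load_profile("stable")

from demsim.calibrate import CalibrationTargets, calibrate
from demsim.inputs import default_synthetic_inputs, load_risk_config
from demsim.model import fit_reference_model


@pytest.fixture(scope="session")
def female_config():
    return load_risk_config("female")


@pytest.fixture(scope="session")
def male_config():
    return load_risk_config("male")


@pytest.fixture(scope="session")
def synthetic_female():
    """Default synthetic life table and incidence schedule (female)."""
    return default_synthetic_inputs("female")


@pytest.fixture(scope="session")
def fitted_female(female_config, synthetic_female):
    """Analytically calibrated model on the default synthetic inputs."""
    table, inc = synthetic_female
    targets = CalibrationTargets.from_config(female_config, table, inc)
    return calibrate(targets, female_config)


@pytest.fixture(scope="session")
def matched_models():
    """Reference-matched calibrated models for both sexes (cached)."""
    return {sex: fit_reference_model(sex) for sex in ("female", "male")}
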