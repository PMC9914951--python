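import numpy as np
import pytest

from drinkoccasion import CoefficientSet, DrinkerProfile, NBParams, ObservationRecord


@pytest.fixture(scope="session")
def reference_coeffs() -> CoefficientSet:
    return CoefficientSet.reference()


@pytest.fixture
def params_half() -> NBParams:
    """The worked-example drinker: two mini episodes, even stopping odds."""
    return NBParams(r=2.0, p=0.5)


@pytest.fixture
def example_profile() -> DrinkerProfile:
    """The worked-example respondent: female, 35-49, K=3, M=20."""
    return DrinkerProfile("35-49", "female", 3, 20)


@pytest.fixture
def make_constant_cohort():
    """Cohorts of identical-profile records with prescribed outcome counts."""

    def _make(y_values, profile=None, censor_at=20):
        profile = profile or DrinkerProfile("20-25", "male", 2, 10)
        return [
            ObservationRecord(profile, int(y), censored=(y >= censor_at))
            for y in y_values
        ]

    return _make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230131)
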