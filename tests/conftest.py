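import warnings

import pytest

from pedqus.cohort import GeneratorParams, generate_cohort, make_fixture_129
from pedqus.qc import apply_exclusions


@pytest.fixture(scope="session")
def fixture_cohort():
    """The packaged 129-child recruitment fixture."""
    return make_fixture_129()


@pytest.fixture(scope="session")
def retained_cohort(fixture_cohort):
    """The 112 children passing the enzyme and BMI filters."""
    retained, _ = apply_exclusions(fixture_cohort)
    return retained


@pytest.fixture(scope="session")
def synth2000():
    """A large synthetic cohort with the default dependence structure."""
    return generate_cohort(GeneratorParams(n=2000, seed=42))


@pytest.fixture
def coded(synth2000):
    """Large cohort with 0/1 codings for sex and cooperation."""
    df = synth2000.copy()
    df["sex01"] = (df.sex == "female").astype(float)
    df["coop01"] = (df.cooperation == "restless").astype(float)
    return df


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
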