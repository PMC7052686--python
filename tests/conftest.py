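import pytest

from bvnlscreen import BVNLScreen, GeneratorConfig, generate_cohort

# One arbitrary but frozen seed for the shared study-condition fixtures; the
# generator defaults themselves (5000 normals, 7 cases, calibrated SDs) are
# the conditions under test and are never varied here.
FIXTURE_SEED = 1234


@pytest.fixture(scope="session")
def generator_config():
    return GeneratorConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def cohort(generator_config):
    """Default synthetic cohort: 5000 normative newborns + 7 affected cases."""
    return generate_cohort(generator_config)


@pytest.fixture(scope="session")
def normative(cohort):
    """The 5000 non-affected rows (normals incl. the pseudo-deficient tail)."""
    return cohort[cohort["status"] != "affected"].reset_index(drop=True)


@pytest.fixture(scope="session")
def fitted_screen(normative):
    """BVNLScreen fitted on the normative rows with default thresholds."""
    return BVNLScreen().fit(normative)


@pytest.fixture(scope="session")
def screen_table(fitted_screen, cohort):
    """Per-sample verdict table for the full cohort."""
    return fitted_screen.screen(cohort)
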