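import pytest
from hypothesis import HealthCheck, settings

from nepartition import fixtures
from nepartition.pipeline import analyze_trial
from nepartition.simulate import NoiseSpec, TrialSpec, generate_trial

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ingredients():
    """The packaged 47-ingredient deposition table."""
    return fixtures.ingredient_table()


@pytest.fixture(scope="session")
def trial_zero():
    """A noise-free synthetic trial under the default study conditions."""
    return generate_trial(TrialSpec(noise=NoiseSpec.zero(), seed=7))


@pytest.fixture(scope="session")
def analysis_zero(trial_zero):
    """Full balance+difference analysis of the noise-free trial."""
    return analyze_trial(trial_zero.records, trial_zero.traces)
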