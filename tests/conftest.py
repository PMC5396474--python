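import pytest
from hypothesis import HealthCheck, settings

from tarsnp.fixtures import FixtureSpec, generate_bundle
from tarsnp.report import load_config, run_screen

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One deterministic synthetic bundle shared across the session."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(FixtureSpec(seed=1), str(out))


@pytest.fixture(scope="session")
def screen_outputs(bundle):
    """Reports of the full screen run on the session bundle."""
    return run_screen(load_config(bundle["config"]))
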