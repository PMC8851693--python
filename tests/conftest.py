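import logging

import pytest
from hypothesis import HealthCheck, settings

import ohpcb

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# The pipeline logs censoring events and estimator fallbacks at INFO; keep the
# test output readable.
logging.getLogger("ohpcb").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_study():
    """The default three-site study at seed 1 (shared across tests)."""
    return ohpcb.generate_study(ohpcb.default_config(seed=1))


@pytest.fixture(scope="session")
def default_results(default_study):
    """Fitted model and concentration table for the default study, seed 1."""
    model, table = ohpcb.analyze_study(default_study, seed=1)
    return {"study": default_study, "model": model, "table": table}


@pytest.fixture(scope="session")
def small_study():
    """A fast two-sample study (IHSC-like preset) for plumbing tests."""
    return ohpcb.generate_study(ohpcb.ihsc_like_preset(seed=5))
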