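import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    from crtmediate import population_defaults

    return population_defaults()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def rep_seeds(master: int, n: int) -> list[int]:
    """Deterministic per-replication data seeds for test harnesses."""
    return [
        int(c.generate_state(1)[0] % 2**31)
        for c in np.random.SeedSequence(master).spawn(n)
    ]
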