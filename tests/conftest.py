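import numpy as np
import pytest

from mutclock import DamageRepairParams, human_like_fixture


@pytest.fixture(scope="session")
def fixture_params():
    """Illustrative human-like replication parameters."""
    return human_like_fixture()


@pytest.fixture
def damage_params():
    """Generic damage--repair rates with efficient repair (R = 1000)."""
    return DamageRepairParams(mu=1e-3, r=1.0)


def brute_force_count(per_division_rates, H):
    """Independent oracle: sum per-division Bernoulli expectations over a lineage."""
    return float(np.sum(per_division_rates)) * H
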