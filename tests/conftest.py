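import numpy as np
import pytest

from guildnet.core_data import OtuTable
from guildnet.synthetic_data import GuildSpec, SyntheticCohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [5, 0, 12, 3],
            [1, 3, 0, 7],
            [9, 2, 4, 0],
        ]
    )
    return OtuTable(("s1", "s2", "s3"), ("o1", "o2", "o3", "o4"), counts)


@pytest.fixture
def random_table(rng):
    counts = rng.integers(0, 50, size=(50, 30))
    return OtuTable(
        tuple(f"s{i}" for i in range(50)),
        tuple(f"o{j}" for j in range(30)),
        counts,
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Two planted guilds + noise; shared by network/guild tests."""
    guilds = GuildSpec(sizes=(8, 6), rho_intra_case=0.7, rho_intra_control=0.7)
    cohort = SyntheticCohortSpec(
        n_case=150, n_control=150, n_noise_otus=20, seed=99
    )
    return generate_cohort(guilds, cohort)
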