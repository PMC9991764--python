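import sys
from pathlib import Path

import pytest

from dietna import GeneratorParams, generate_cohort, zero_noise_params

# make the oracle module importable as plain `oracles`
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture(scope="session")
def small_bundle():
    """A small default-conditions cohort shared by read-only tests."""
    return generate_cohort(GeneratorParams(n_participants=60, seed=7))


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Degenerate cohort in which every instrument is error-free."""
    return generate_cohort(zero_noise_params(n_participants=24, seed=11))
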