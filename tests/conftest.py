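import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))   # makes `oracles` importable

from sfanet.synthetic import SynthParams, generate_dataset


@pytest.fixture(scope="session")
def small_params():
    """Fast-rendering generator settings used across the suite."""
    return SynthParams(size=64)


@pytest.fixture(scope="session")
def small_samples(small_params):
    return generate_dataset(4, small_params, seed=101)
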