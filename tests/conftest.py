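import sys
from pathlib import Path

import pytest

# make the oracle helpers importable as a plain module
sys.path.insert(0, str(Path(__file__).parent))

from chukchi_carbon.synthetic import ScenarioSpec  # noqa: E402


@pytest.fixture
def spec_noise_free() -> ScenarioSpec:
    """Generator spec with all stochastic spread switched off."""
    return ScenarioSpec(seed=0, noise=0.0)


@pytest.fixture
def spec_default() -> ScenarioSpec:
    return ScenarioSpec(seed=42)
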