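import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from holcwells import CityConfig, generate_study


@pytest.fixture(scope="session")
def confounded_city():
    """One mid-size confounded city reused by read-only tests."""
    return generate_study(CityConfig(seed=11))


@pytest.fixture(scope="session")
def null_city():
    """A city where grade carries no causal effect and no confounding."""
    return generate_study(
        CityConfig(grade_log_step=0.0, confounder_sd=0.0, seed=12)
    )
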