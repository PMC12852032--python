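import numpy as np
import pytest

from c2pkpd import default_generator_config


@pytest.fixture(scope="session")
def defaults():
    """Frozen default study conditions: (model, pk_design, outcome_design)."""
    return default_generator_config()


@pytest.fixture(scope="session")
def nominal_times():
    """The study's nine nominal post-dose sampling times, in days."""
    return np.array([5 / 1440, 0.25, 1.0, 2.0, 3.0, 5.0, 7.0, 14.0, 21.0])
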