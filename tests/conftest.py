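import numpy as np
import pytest

import dsampsize as dz


@pytest.fixture(scope="session")
def censored_sample():
    """Moderate simulated dataset: beta=1, 264 events, 20% censoring."""
    rng = np.random.default_rng(2024)
    spec = dz.SimulationSpec(beta=1.0, target_events=264, target_censoring=0.2)
    return dz.exact_event_dataset(spec, rng=rng)


@pytest.fixture(scope="session")
def uncensored_sample():
    """Small fully observed dataset: beta=0.8, 120 events."""
    rng = np.random.default_rng(77)
    spec = dz.SimulationSpec(beta=0.8, target_events=120, target_censoring=0.0)
    return dz.exact_event_dataset(spec, rng=rng)
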