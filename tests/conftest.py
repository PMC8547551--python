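import numpy as np
import pytest

from ventcontrol import BaselineInputs


@pytest.fixture
def pooled_baseline() -> BaselineInputs:
    """Pooled control-condition anchors: 206 ml/min, 38.2 mmHg, 33.5 mmHg."""
    return BaselineInputs()


def random_valid_systems(rng: np.random.Generator, size: int):
    """Random (vco2, gain, apnea_threshold) triples spanning physiology-like ranges."""
    vco2 = rng.uniform(100.0, 300.0, size)
    gain = rng.uniform(0.2, 5.0, size)
    at = rng.uniform(20.0, 50.0, size)
    return vco2, gain, at
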