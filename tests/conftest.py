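import numpy as np
import pytest

from biofoulmon import ScenarioConfig


@pytest.fixture
def tiny_config():
    """A fast fouling scenario at 128×192 px, 6 h frames."""
    return ScenarioConfig.scaled(
        128, 192, seed=7, duration_h=240.0, onset_h=96.0, frame_interval_h=6.0
    )


@pytest.fixture
def null_config():
    """Same geometry, no fouling at all."""
    return ScenarioConfig.scaled(
        128, 192, seed=7, duration_h=240.0, onset_h=96.0,
        frame_interval_h=6.0, nucleation_rate=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
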