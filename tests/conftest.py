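import numpy as np
import pytest

import gammappi as g


@pytest.fixture(scope="session")
def scaled_design():
    """Desk-scale session layout used throughout the suite (240/180/480 s, 500 Hz)."""
    return g.scaled_design()


@pytest.fixture(scope="session")
def null_session(scaled_design):
    """A session with no drug effect (all gains 1, true PPI 60)."""
    return g.generate_session(scaled_design, g.EffectSpec(), seed=11)


@pytest.fixture(scope="session")
def elevated_session(scaled_design):
    """Ongoing-gamma amplitude raised by sqrt(2) (power x2) post-injection."""
    return g.generate_session(
        scaled_design, g.EffectSpec(ongoing_gain=float(np.sqrt(2))), seed=12
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
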