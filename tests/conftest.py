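import numpy as np
import pytest

from cinphot import (
    SynthConfig,
    demultiplex,
    generate_pavlovian_session,
    isosbestic_correct,
)


@pytest.fixture(scope="session")
def pav_session():
    """One mid-sized Pavlovian session with default noise, shared across tests."""
    cfg = SynthConfig(seed=11, session_duration=300.0)
    return generate_pavlovian_session(cfg)


@pytest.fixture(scope="session")
def corrected(pav_session):
    """Isosbestic-corrected dopamine-channel trace of the shared session."""
    traces = {tr.label: tr for tr in demultiplex(pav_session.raw, pav_session.schedule)}
    return isosbestic_correct(traces["rdlight"], traces["iso"])


@pytest.fixture(scope="session")
def channel_traces(pav_session):
    return {tr.label: tr for tr in demultiplex(pav_session.raw, pav_session.schedule)}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
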