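"""Shared fixtures: packaged-construct sweep sets simulated once per session."""

import pytest

from ikstools import AnalysisConfig, simulate_single_channel_sweeps
from ikstools import constructs as C

EQ_SEED = 20123
EQQ_SEED = 20124


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def eq_set():
    """100 EQ sweeps at +60 mV with the packaged gating model."""
    return simulate_single_channel_sweeps(
        C.SINGLE_CHANNEL["EQ"], C.single_channel_protocol("EQ"),
        n_sweeps=100, fs=10_000.0, seed=EQ_SEED, construct="EQ")


@pytest.fixture(scope="session")
def eqq_set():
    """100 EQQ sweeps at +60 mV with the packaged gating model."""
    return simulate_single_channel_sweeps(
        C.SINGLE_CHANNEL["EQQ"], C.single_channel_protocol("EQQ"),
        n_sweeps=100, fs=10_000.0, seed=EQQ_SEED, construct="EQQ")
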