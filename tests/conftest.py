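"""Shared fixtures: calibrated behavior chains and session configurations."""

import numpy as np
import pytest

import interbrain as ib


@pytest.fixture(scope="session")
def one_chamber_chain():
    """Joint behavior chain calibrated to same-behavior probability 0.58."""
    return ib.synth_transition_matrix(ib.SynthChainSpec(target_same_prob=0.58))


@pytest.fixture(scope="session")
def two_chamber_chain():
    """Independent-subjects product chain (no coordination)."""
    return ib.synth_transition_matrix(ib.SynthChainSpec(coordination=0.0))


@pytest.fixture(scope="session")
def one_chamber_config():
    return ib.RunConfig()


@pytest.fixture(scope="session")
def two_chamber_config():
    return ib.RunConfig().two_chambers_variant()


@pytest.fixture(scope="session")
def one_chamber_session(one_chamber_config, one_chamber_chain):
    """A single representative coupled session."""
    return ib.simulate_session(one_chamber_config, one_chamber_chain, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dyad(rng, n_bins=200, dt=2.5):
    """A generic random 2-subject activity series."""
    return ib.ActivityTimeSeries(
        times=np.arange(n_bins) * dt,
        values=rng.standard_normal((2, n_bins)),
        subject_ids=("bat1", "bat2"),
    )
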