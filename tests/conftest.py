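import numpy as np
import pytest

from spindlesync import (
    SphericalHeadModel,
    build_sensor_array,
    build_source_space,
    assemble_gain,
)


@pytest.fixture(scope="session")
def head():
    return SphericalHeadModel()


@pytest.fixture(scope="session")
def eeg_array(head):
    return build_sensor_array("EEG", head, seed=1)


@pytest.fixture(scope="session")
def meg_array(head):
    return build_sensor_array("MEG", head, seed=1)


@pytest.fixture(scope="session")
def small_source_space():
    """128-source folded space for fast unit tests."""
    return build_source_space(64, fold_amplitude=0.1, fold_wavenumber=12, seed=2)


@pytest.fixture(scope="session")
def desk_source_space():
    """The desk-scale analysis space: 642 dipoles per hemisphere."""
    return build_source_space(642, fold_amplitude=0.1, fold_wavenumber=12, seed=5)


@pytest.fixture(scope="session")
def desk_gain_meg(desk_source_space, meg_array, head):
    return assemble_gain(desk_source_space, meg_array, head)


@pytest.fixture(scope="session")
def desk_gain_eeg(desk_source_space, eeg_array, head):
    return assemble_gain(desk_source_space, eeg_array, head)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
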