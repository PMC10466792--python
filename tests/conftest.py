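import numpy as np
import pytest

from hemibalance.records import BlockParadigm, FnirsRecording, default_montage
from hemibalance.simulate import (
    NoiseConfig,
    SimulationConfig,
    paradigm_marks,
    simulate_recording,
    simulate_truth,
)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def paradigm():
    return BlockParadigm()


@pytest.fixture
def sim_config():
    return SimulationConfig(n_subjects=4)


@pytest.fixture
def silent_noise():
    return NoiseConfig().silent()


def make_recording(data: np.ndarray, montage, fs: float = 11.0,
                   paradigm: BlockParadigm | None = None) -> FnirsRecording:
    """Wrap a (26, 2, n) intensity array as a valid recording."""
    paradigm = paradigm or BlockParadigm()
    marks = paradigm_marks(paradigm, fs)
    return FnirsRecording(subject_id="s1", timepoint="T1", sampling_rate=fs,
                          intensities=data, marks=marks, montage=montage)


@pytest.fixture
def clean_recording(montage, sim_config, silent_noise):
    """One noise-free synthetic recording with its generating truth."""
    truth = simulate_truth(sim_config, seed=11)[0]
    rec = simulate_recording(truth, "T1", sim_config, seed=11,
                             montage=montage, noise=silent_noise)
    return rec, truth
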