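import numpy as np
import pytest

from oscana import synthgen
from oscana.recording import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def white_pair(rng):
    """Independent white-noise series, 20 s at 100 Hz."""
    n = 2000
    return rng.standard_normal(n), rng.standard_normal(n)


@pytest.fixture
def small_recording(rng):
    return Recording(rng.standard_normal((4, 500)), fs=100.0)


@pytest.fixture(scope="session")
def clean_coupled_pair():
    """Noiseless coupled pair (d=0.5) shared across tests: 60 s at 1 kHz."""
    spec = synthgen.CouplingSpec(
        coupling_depth=0.5, noise_sd=0.0, coherence_mix=1.0,
        duration=60.0, fs=1000.0, seed=11,
    )
    a, b = synthgen.gen_coupled_pair(spec)
    return spec, a, b


@pytest.fixture(scope="session")
def microstate_truth():
    """4-class switching EEG at SNR 5 plus its ground-truth labels."""
    topo = synthgen.random_topographies(19, 4, seed=5)
    spec = synthgen.MicrostateSpec(
        n_channels=19, topographies=topo, mean_dwell=100.0,
        fs=250.0, duration=40.0, snr=5.0, seed=6,
    )
    rec, labels = synthgen.gen_microstate_eeg(spec)
    return spec, rec, labels


def label_agreement(true_labels, est_labels, k):
    """Best label agreement up to class permutation (Hungarian matching)."""
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((k, k))
    np.add.at(conf, (np.asarray(true_labels), np.asarray(est_labels)), 1)
    rows, cols = linear_sum_assignment(-conf)
    return conf[rows, cols].sum() / len(true_labels)
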