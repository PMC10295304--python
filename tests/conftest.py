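import numpy as np
import pytest

from ratresp import BlobSpec, EcgSpec, generate_breathing_masks, generate_rat_ecg


@pytest.fixture(scope="session")
def blob_default():
    """30 s @ 60 fps breathing blob at 96 breaths/min with drift and two
    step artifacts — the standard camera-branch fixture."""
    spec = BlobSpec(duration_s=30.0, rr_true=96.0,
                    artifact_times=(10.0, 20.0), seed=7)
    seq, truth = generate_breathing_masks(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def blob_clean():
    """Artifact- and noise-free blob for spectral-fidelity checks."""
    spec = BlobSpec(duration_s=30.0, rr_true=96.0, drift_amplitude=0.0,
                    noise_sd=0.0, seed=1)
    seq, truth = generate_breathing_masks(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def ecg_default():
    """60 s rat ECG, hr 360 bpm, rr 96, 30% amplitude modulation."""
    spec = EcgSpec(seed=3)
    ecg, truth = generate_rat_ecg(spec)
    return spec, ecg, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
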