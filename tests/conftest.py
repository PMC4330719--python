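import warnings

import numpy as np
import pytest

import chirpdecode as cd


@pytest.fixture(scope="session")
def fir_spec():
    return cd.design_fir_bandpass(2.0, 30.0, 496, 300.0)


@pytest.fixture(scope="session")
def clean_session():
    """Artifact-off 16-channel session, no planted faults."""
    cfg = cd.SessionConfig(n_channels=16, n_chirp=60, seed=8)
    return cd.simulate_recording(cfg)


@pytest.fixture(scope="session")
def clean_filtered(fir_spec, clean_session):
    rec, _ = clean_session
    return cd.apply_filter(fir_spec, rec)


@pytest.fixture(scope="session")
def high_snr_session():
    """High-SNR artifact-off session at full protocol scale (16 channels)."""
    cfg = cd.SessionConfig(n_channels=16, n_chirp=200, erp_snr=2.0, seed=11)
    return cd.simulate_recording(cfg)


@pytest.fixture(scope="session")
def toy_ica_decomposition():
    """Extended infomax fitted on a known 3-source mixture."""
    rng = np.random.default_rng(0)
    n = 300 * 60
    s1 = rng.uniform(-np.sqrt(3), np.sqrt(3), n)              # sub-Gaussian
    s2 = rng.laplace(0.0, 1.0 / np.sqrt(2), n)                # super-Gaussian
    s3 = np.sqrt(2) * np.sin(2 * np.pi * 7 * np.arange(n) / 300 + 0.3)
    S = np.vstack([s1, s2, s3])
    A = rng.normal(size=(3, 3))
    X = A @ S
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        decomp = cd.fit_extended_infomax(X, seed=1)
    return decomp, A, X
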