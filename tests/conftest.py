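import numpy as np
import pytest

import nirstate as ns

# Table of per-subject decoding accuracies bundled with the package;
# duplicated here as plain lists for hand-verifiable assertions.
CALIBRATION = [80, 88, 83, 82, 95, 95, 100, 75, 95, 90, 80, 100]
ONLINE = [50, 42, 70, 75, 41, 78, 60, 55, 78]  # n = 9, three sessions missing


@pytest.fixture(scope="session")
def montage():
    return ns.default_montage()


@pytest.fixture(scope="session")
def high_snr_session():
    """One simulated task session with the default (classifiable) SNR."""
    cfg = ns.SimConfig(seed=11)
    rec, truth = ns.simulate_session(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def noiseless_session():
    """Activation only, all noise terms zero: used for exact-recovery checks."""
    cfg = ns.SimConfig(
        seed=3,
        noise=ns.NoiseSpec(
            cardiac_amp=0.0, respiration_amp=0.0, mayer_amp=0.0,
            drift_slope=0.0, white_sd=0.0,
        ),
    )
    rec, truth = ns.simulate_session(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def feature_matrix(high_snr_session):
    """Features from the shared high-SNR session (21 epochs x 160 columns)."""
    _cfg, rec, _truth = high_snr_session
    return ns.process_recording(rec)


def random_feature_matrix(rng, n_epochs=20, n_features=12):
    """Pure-noise features with balanced labels."""
    labels = (["relax", "nback"] * (n_epochs // 2 + 1))[:n_epochs]
    return ns.FeatureMatrix(
        values=rng.normal(size=(n_epochs, n_features)),
        labels=labels,
        column_names=[f"f{i}" for i in range(n_features)],
    )
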