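import numpy as np
import pytest

import voltphys as vp


@pytest.fixture(scope="session")
def protocol():
    """Default sweep protocol: 600 Hz, 0.5 s baseline, 1 s 20 Hz Op, 1 s post."""
    return vp.make_protocol()


@pytest.fixture(scope="session")
def short_protocol():
    """Shorter sweep to keep movie-rendering tests light."""
    return vp.make_protocol(baseline_s=0.3, post_s=0.5)


@pytest.fixture(scope="session")
def noisefree_locked(protocol):
    """Noise-free pulse-locked firing sweep with its ground truth."""
    trace, gt = vp.simulate_trace("locked_single_ap", protocol,
                                  noise_sd=0.0, seed=1, artifacts=False)
    return trace, gt


@pytest.fixture(scope="session")
def two_blob_features():
    """Two well-separated Gaussian feature blobs (n=100 each, 10 SD apart)."""
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(0.0, 1.0, (100, 29)),
                   rng.normal(10.0, 1.0, (100, 29))])
    truth = np.repeat([0, 1], 100)
    return X, truth
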