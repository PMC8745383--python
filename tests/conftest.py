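import numpy as np
import pytest

from smls.simulate import (
    AcquisitionContext, FluorophoreModel, GFP_CONTEXT, GroundTruthSpot,
)


@pytest.fixture
def gfp():
    return FluorophoreModel(157.0, 65.0)


@pytest.fixture
def quiet_context():
    """Noise-free camera: deterministic expected images."""
    return AcquisitionContext(read_noise_sd=0.0, baseline=0.0)


@pytest.fixture
def snr10_context():
    """Camera conditions giving peak SNR ~ 10 for a 157-count spot."""
    return GFP_CONTEXT


def make_spot(x, y, signal, z=0.0, n_copies=1):
    return GroundTruthSpot(x=x, y=y, z=z, n_copies=n_copies,
                           true_integrated_signal=signal)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
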