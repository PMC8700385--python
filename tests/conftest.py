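import numpy as np
import pytest

from ivimfusion.core import AcquisitionScheme, ivim_signal
from ivimfusion.synthetic import NoiseModel, add_rician_noise

# central-tendency truths used across tests (lesion / normal PZ tissue)
LESION_TRUTH = {"f": 0.427, "d": 0.51e-3, "dstar": 3.73e-3, "s0": 100.0}
NORMAL_TRUTH = {"f": 0.521, "d": 0.80e-3, "dstar": 4.31e-3, "s0": 100.0}


@pytest.fixture(scope="session")
def scheme():
    return AcquisitionScheme()


@pytest.fixture(scope="session")
def lesion_curve(scheme):
    """Noise-free decay at the lesion truth."""
    return ivim_signal(scheme.array, **LESION_TRUTH)


def noisy_voxels(truth, snr, n, seed, scheme=None):
    """(n, n_b) Rician-noisy replicate voxels at one ground truth."""
    scheme = scheme or AcquisitionScheme()
    clean = ivim_signal(scheme.array, **truth)
    stack = np.tile(clean, (n, 1))
    return add_rician_noise(stack, NoiseModel(snr=snr, seed=seed, s0_ref=truth["s0"]))
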