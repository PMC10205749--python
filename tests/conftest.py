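import numpy as np
import pytest

from oligokin.coagulation import KernelParams, monomer_distribution
from oligokin.scattering import calibrate_from_monomer


@pytest.fixture
def best_fit_kernel():
    """Kernel at the published best-fit point for 1.5 mM peptide."""
    return KernelParams(r0=0.0054, e0=120.0, nth=16.0)


@pytest.fixture
def cal_15mm():
    """Calibration from the 0.015 V monomer signal at 1.5 mM."""
    return calibrate_from_monomer(0.015, 1.5)


@pytest.fixture
def small_monomer_start():
    return monomer_distribution(1.0, 128)


@pytest.fixture
def constant_kernel():
    """Size-independent kernel override, K = 2 mM^-1 s^-1."""
    K = 2.0

    def kernel(n, m):
        return np.full(np.broadcast_shapes(np.shape(n), np.shape(m)), K)

    kernel.K = K
    return kernel
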