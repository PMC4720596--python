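import numpy as np
import pytest

from kdespike import KSpaceSeries, images_to_kspace


def complex_randn(rng, *shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


def planted_matrix(rng, m=40, n=40, rank=2, support_frac=0.05, spike_mag=10.0):
    """Known low-rank + sparse decomposition: the oracle for solver tests."""
    L0 = complex_randn(rng, m, rank) @ complex_randn(rng, rank, n)
    S0 = np.zeros((m, n), dtype=complex)
    k = int(round(support_frac * m * n))
    idx = rng.choice(m * n, size=k, replace=False)
    S0.flat[idx] = spike_mag * np.exp(1j * rng.uniform(0, 2 * np.pi, k))
    return L0, S0


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def lowrank_series(rng):
    """Noiseless genuinely low-rank k-space series: 6 frames that are
    scalar multiples of one 32x32 base spectrum."""
    base = np.zeros((32, 32))
    base[10:22, 12:20] = 1.0
    base[14:18, 14:18] = 2.5
    scales = np.linspace(0.6, 1.4, 6)
    images = base[:, :, None] * scales[None, None, :]
    return KSpaceSeries(images_to_kspace(images))
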