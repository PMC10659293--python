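import numpy as np
import pytest

from sfsc import RealGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_dft(x: np.ndarray) -> np.ndarray:
    """O(N^2) unitary DFT by explicit matrix multiply (1-D oracle)."""
    n = len(x)
    k = np.arange(n)
    F = np.exp(-2j * np.pi * np.outer(k, k) / n) / np.sqrt(n)
    return F @ x


def brute_force_shell_indices(shape):
    """Enumerate (multi-index, shell label) over the inscribed Nyquist ball."""
    out = {}
    for idx in np.ndindex(*shape):
        k = [i - n if i >= n // 2 + n % 2 else i for i, n in zip(idx, shape)]
        rad = np.sqrt(sum(v * v for v in k))
        if rad > min(shape) / 2:
            continue
        out.setdefault(int(round(rad)), []).append(idx)
    return out


@pytest.fixture
def random_grid(rng):
    def make(shape, voxel_size=1.0):
        return RealGrid(rng.normal(size=shape), voxel_size)

    return make
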