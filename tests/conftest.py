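import numpy as np
import pytest

from conncca.envelope import RegionTimeSeries


def random_spd(order: int, rng: np.random.Generator,
               eig_low: float = 0.5, eig_high: float = 2.0) -> np.ndarray:
    """SPD matrix with eigenvalues log-uniform in [eig_low, eig_high]."""
    Q, _ = np.linalg.qr(rng.standard_normal((order, order)))
    w = np.exp(rng.uniform(np.log(eig_low), np.log(eig_high), size=order))
    return (Q * w) @ Q.T


def random_invertible(order: int, rng: np.random.Generator) -> np.ndarray:
    """Well-conditioned invertible matrix (singular values in [0.5, 2])."""
    Q1, _ = np.linalg.qr(rng.standard_normal((order, order)))
    Q2, _ = np.linalg.qr(rng.standard_normal((order, order)))
    s = rng.uniform(0.5, 2.0, size=order)
    return (Q1 * s) @ Q2


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def sine_ts() -> RegionTimeSeries:
    """Two-region series: 10 Hz and 50 Hz unit sinusoids at 250 Hz."""
    fs = 250.0
    t = np.arange(int(20 * fs)) / fs
    values = np.stack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 50 * t)], axis=1)
    return RegionTimeSeries(values=values, sampling_rate=fs, labels=["a", "b"])
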