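import numpy as np
import pytest

from dapnet.synthetic import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 phantoms per class at 32x32 - shared, read-only."""
    return generate_dataset({"benign": 12, "malignant": 12, "normal": 12},
                            seed=7, size=32)


def random_psd(rng, d: int, cond: float = 100.0, trace_one: bool = True) -> np.ndarray:
    """Random symmetric PSD with log-uniform spectrum of condition <= cond."""
    q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    lam = np.exp(rng.uniform(0.0, np.log(cond), size=d))
    m = (q * lam) @ q.T
    m = (m + m.T) / 2.0
    if trace_one:
        m = m / np.trace(m)
    return m
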