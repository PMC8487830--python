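import numpy as np
import pytest

from voxfatigue.preprocess import AudioSignal
from voxfatigue.synthetic import SyntheticCorpusSpec, generate_corpus, generate_fgn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small balanced two-class corpus for classifier/pipeline tests."""
    spec = SyntheticCorpusSpec(n_per_class=30, seed=7)
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def fgn_grid():
    """fGn draws over the Hurst grid: {H: array of 20 series, n=8192}."""
    return {
        h: np.stack([generate_fgn(8192, h, seed) for seed in range(20)])
        for h in (0.2, 0.35, 0.5, 0.65, 0.8)
    }


@pytest.fixture
def speechlike_signal():
    """A single 1/f-type test signal, long enough for every stage."""
    x = np.cumsum(generate_fgn(16000, 0.7, seed=3))
    return AudioSignal(samples=x / np.max(np.abs(x)), rate=16000)
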