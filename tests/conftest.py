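import numpy as np
import pytest

from chromaroi.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_set():
    """14-sample 3x3-grid synthetic set with one planted cell at (2, 2)."""
    spec = SyntheticSpec(
        n_samples=14,
        height=60,
        width=96,
        roi1=3,
        roi2=3,
        informative_cells=((2, 2),),
        peaks_per_cell=2,
        peak_sigma=2.5,
        seed=7,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def tiny_set():
    """10-sample 2x2-grid set for exhaustive-subset comparisons."""
    spec = SyntheticSpec(
        n_samples=10,
        height=40,
        width=64,
        roi1=2,
        roi2=2,
        informative_cells=((1, 2),),
        peaks_per_cell=2,
        peak_sigma=2.5,
        seed=3,
    )
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
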