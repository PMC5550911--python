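import numpy as np
import pytest

from lfquant import QuantParams, SynthConfig


@pytest.fixture
def params() -> QuantParams:
    return QuantParams()


@pytest.fixture
def small_cfg() -> SynthConfig:
    """A quick-to-generate study-shaped config (5 vs 5 replicates)."""
    return SynthConfig(n_proteins=120, seed=42)


@pytest.fixture
def flat_rt() -> np.ndarray:
    return np.arange(0.0, 600.0, 0.5)


def gaussian_trace(rt: np.ndarray, apex: float, sigma: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((rt - apex) / sigma) ** 2)
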