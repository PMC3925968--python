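import numpy as np
import pytest

THREE_PEAK_MEANS = (0.10, 0.28, 0.63)
THREE_PEAK_SDS = (0.04, 0.05, 0.08)
THREE_PEAK_WEIGHTS = (0.3, 0.3, 0.4)


def draw_three_peak_sample(seed: int, n: int = 450) -> np.ndarray:
    """Efficiency sample from the canonical three-peak mixture."""
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n, p=THREE_PEAK_WEIGHTS)
    return rng.normal(
        np.asarray(THREE_PEAK_MEANS)[comp], np.asarray(THREE_PEAK_SDS)[comp]
    )


@pytest.fixture
def three_peak_sample():
    return draw_three_peak_sample(seed=0)
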