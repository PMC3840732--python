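import numpy as np
import pytest

from gradclean import Recording, SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_synth():
    """A small default-protocol synthetic recording with ground truth."""
    spec = SyntheticSpec(n_v=6, n_channels=2, pre_duration=6.0,
                         post_duration=6.0, seed=11)
    return generate(spec)


@pytest.fixture(scope="session")
def gap_synth():
    """Synthetic recording with volume gaps between slice groups."""
    spec = SyntheticSpec(n_v=6, n_channels=2, pre_duration=6.0,
                         post_duration=6.0, volume_gap=0.288, seed=12)
    return generate(spec)


@pytest.fixture
def tiny_recording():
    rng = np.random.default_rng(0)
    return Recording(
        data=rng.standard_normal((2, 100)),
        rate=100.0,
        channel_labels=["C3", "C4"],
    )
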