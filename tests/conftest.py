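import numpy as np
import pytest

from perceptseg import inference, simulate


@pytest.fixture(scope="session")
def stim2() -> inference.Stimulus:
    return inference.Stimulus("fixture", K=2)


@pytest.fixture(scope="session")
def gt2() -> "simulate.SegMap":
    return simulate.make_ground_truth_map(2, seed=1)


@pytest.fixture(scope="session")
def clean_block(gt2, stim2) -> inference.BlockData:
    """A well-behaved synthetic block: high-certainty observer, 2x schedule."""
    obs = simulate.ObserverParams(ground_truth=gt2, certainty=0.9, lapse=0.05, seed=1)
    return simulate.simulate_observer_block(obs, stim2, n_trials=450)


@pytest.fixture(scope="session")
def halfsplit_map() -> np.ndarray:
    """15x15 labels: left half 1, right half 2 (near-equal marginals)."""
    labels = np.ones((15, 15), dtype=int)
    labels[:, 8:] = 2
    return labels
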