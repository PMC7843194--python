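import numpy as np
import pytest

from sdaeconn import Recording, chain_spec, generate


@pytest.fixture(scope="session")
def chain_recording():
    """Default planted-chain recording (1->2->3->4), short for unit tests."""
    rec, adj = generate(chain_spec(seed=11, duration=20.0))
    return rec, adj


@pytest.fixture()
def small_recording():
    rng = np.random.default_rng(42)
    return Recording(data=rng.standard_normal((4, 600)), fs=100.0,
                     labels=["a", "b", "c", "d"])


@pytest.fixture()
def grid_recording():
    """5x5 grid recording with montage for Laplacian tests."""
    from sdaeconn import make_grid_montage

    rng = np.random.default_rng(7)
    labels = [f"e{r}_{c}" for r in range(5) for c in range(5)]
    montage = make_grid_montage(5, 5, labels=labels)
    return Recording(data=rng.standard_normal((25, 200)), fs=100.0,
                     labels=labels, montage=montage)
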