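import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from rotwave import PopulationDataset, WaveModelParams, generate_dataset


@pytest.fixture(scope="session")
def wave_ds():
    """Noise-free travelling wave at the reference parameters."""
    return generate_dataset(WaveModelParams())


@pytest.fixture(scope="session")
def small_wave_ds():
    """A quick small wave for plumbing tests."""
    return generate_dataset(
        WaveModelParams(n_neurons=40, n_time=80, n_conditions=3, a=10.0, b=1.5, sigma=6.0)
    )


@pytest.fixture
def tiny_ds():
    """Hand-sized dataset with distinct values for IO round trips."""
    rng = np.random.default_rng(7)
    return PopulationDataset(
        rng.normal(size=(2, 10, 3)),
        dt_ms=2.5,
        event_index=4,
        condition_labels=("left", "right"),
        neuron_ids=("a", "b", "c"),
    )


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    import matplotlib.pyplot as plt

    plt.close("all")
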