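import numpy as np
import pytest

import submitoloc as sm


@pytest.fixture(scope="session")
def small_dataset():
    """A small but learnable 4-class synthetic dataset (20/class)."""
    spec = sm.SyntheticSpec(
        n_per_class=(20, 20, 20, 20),
        length_range=(80, 150),
        effect_size=4.0,
        seed=7,
    )
    records, profiles = sm.generate(spec)
    return records, profiles


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    """Encoded feature matrix and labels for the small dataset."""
    records, _ = small_dataset
    frame = sm.encode_dataset(records)
    labels = frame.pop("label").to_numpy()
    return frame.to_numpy(dtype=float), labels, list(frame.columns)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
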