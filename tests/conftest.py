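import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from eegemotion import ElectrodeLayout, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def layout():
    return ElectrodeLayout.default()


@pytest.fixture(scope="session")
def small_trials():
    """One synthetic subject, 8 trials, clearly separable classes."""
    cfg = SynthConfig(n_subjects=1, n_trials_per_subject=8, effect_size=1.0, seed=11)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
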