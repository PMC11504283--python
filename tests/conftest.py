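import numpy as np
import pytest

from mercl import pipeline, synth


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 4-class dataset: 3 trials per class, one 4 s block each."""
    return synth.generate(synth.SynthSpec(n_trials_per_class=3,
                                          trial_len_s=4.0, seed=7))


@pytest.fixture(scope="session")
def tiny_features(tiny_dataset):
    return pipeline.build_features(tiny_dataset.trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
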