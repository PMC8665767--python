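import warnings

import numpy as np
import pytest

from nasdeconv import ConvTSSModel, generate_archetypes, simulate
from nasdeconv.simulate import make_tss_training_set


@pytest.fixture(scope="session")
def archetypes():
    return generate_archetypes(62, seed=1)


@pytest.fixture(scope="session")
def small_dataset(archetypes):
    """A compact simulated dataset shared by unit tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate(archetypes, n_genes=120, seed=7)


@pytest.fixture(scope="session")
def tss_model(archetypes):
    """Conv classifier trained on labelled TSSs from an independent simulation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train = simulate(archetypes, n_genes=250, seed=301)
    feats, labels, _ = make_tss_training_set(train, seed=302)
    return ConvTSSModel(seed=1).fit(feats, labels)
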