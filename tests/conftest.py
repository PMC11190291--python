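import numpy as np
import pytest

from cbellw import datasets, inference

DATASETS = ("covid19", "head_neck", "bladder", "bone", "guinea_pigs")


@pytest.fixture(scope="session")
def samples():
    """All bundled samples, loaded once."""
    return {name: datasets.load(name).values for name in DATASETS}


@pytest.fixture(scope="session")
def cbellw_fits(samples):
    """CBellW maximum-likelihood fits of all five bundled samples."""
    return {
        name: inference.fit_mle(x, model="cbellw", n_starts=6, seed=1)
        for name, x in samples.items()
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240529)
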