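import numpy as np
import pytest

from domainsalvage import synth
from domainsalvage.data import SplitSpec, split_dataset


@pytest.fixture(scope="session")
def digit_domains():
    """Two small digit-like domains with a strong style shift."""
    spec = synth.TaskSpec(task="digitlike", n_per_domain=400, seed=11)
    return synth.make_domains(spec, synth.strong_shift_pair())


@pytest.fixture(scope="session")
def digit_splits(digit_domains):
    return [split_dataset(d, SplitSpec(seed=1)) for d in digit_domains]


@pytest.fixture(scope="session")
def opacity_domains():
    spec = synth.TaskSpec(task="opacitylike", n_per_domain=240, seed=7)
    return synth.make_domains(spec, synth.strong_shift_pair())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
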