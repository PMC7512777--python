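import numpy as np
import pytest

import gpselect as g


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def model1_dataset():
    """One Model-1 replicate at full study size."""
    return g.generate(g.SimDesign(n=300, model_id=1, exact_n1=True,
                                  x_mode="grid", seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A small selection dataset for cheap end-to-end runs."""
    return g.generate(g.SimDesign(n=60, target_n1=30, model_id=1,
                                  exact_n1=True, x_mode="grid", seed=4))
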