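import numpy as np
import pytest

from ringfit import binding, synthgen


@pytest.fixture
def biphasic_dataset():
    """Default biphasic titration (corners 56/158 nt per ring, 2% noise)."""
    return synthgen.gen_titration(seed=7)


@pytest.fixture
def isotherm_truth():
    """A well-conditioned two-phase isotherm for fit-recovery studies."""
    return binding.BindingModel(tq1=0.45, tq2=0.75, k1=5e-3, k2=2e-4, protein_nM=50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
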