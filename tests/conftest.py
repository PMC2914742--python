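import numpy as np
import pytest

from crowdfold.model import ProteinModel


@pytest.fixture
def model() -> ProteinModel:
    return ProteinModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20100803)


@pytest.fixture
def flat_model() -> ProteinModel:
    """Model with all bin energies zero (walls only): flat potential control."""
    return ProteinModel(nonnative_energies=(0.0,) * 5, urea_intercept=0.0, urea_slope=0.0)
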