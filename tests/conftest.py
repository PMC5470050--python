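import numpy as np
import pytest

from alcocyte.constants import default_constants
from alcocyte.model import ExperimentConfig, PyruvateRegime
from alcocyte.rates import EnzymeLevel


@pytest.fixture(scope="session")
def constants():
    return default_constants()


def make_enzymes(adh=100.0, ald=30.0, ldh=150.0, hct=0.25):
    """Enzyme levels from suspension-scale activities (nkat/ml)."""
    return {
        e: EnzymeLevel.from_activity(e, a, hematocrit=hct)
        for e, a in (("ADH", adh), ("ALD", ald), ("LDH", ldh))
    }


@pytest.fixture
def small_config():
    """A modest alcocyte run with a pyruvate bolus (fully conservative)."""
    hct = 0.25
    return ExperimentConfig(
        enzymes=make_enzymes(hct=hct),
        hematocrit=hct,
        nad0_uM=40.0,
        ethanol0_mM=10.0,
        pyruvate_regime=PyruvateRegime.bolus(initial_mM=5.0),
        duration_h=2.0,
        sampling_grid_h=np.linspace(0, 2.0, 41),
    )


@pytest.fixture
def clamp_config():
    hct = 0.25
    return ExperimentConfig(
        enzymes=make_enzymes(hct=hct),
        hematocrit=hct,
        nad0_uM=40.0,
        ethanol0_mM=10.0,
        pyruvate_regime=PyruvateRegime.clamp(target_uM=100.0),
        duration_h=2.0,
        sampling_grid_h=np.linspace(0, 2.0, 41),
    )
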