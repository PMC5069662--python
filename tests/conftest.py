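import warnings
from dataclasses import replace

import numpy as np
import pytest

from timeskit.synthetic_data import generate_experiment_set, reference_scenarios

# curve_fit on noisy tails legitimately explores bad parameter regions
warnings.filterwarnings("ignore", message="overflow encountered in exp")
warnings.filterwarnings("ignore", message="Covariance of the parameters")


@pytest.fixture(scope="session")
def scenarios():
    return reference_scenarios()


@pytest.fixture(scope="session")
def trypsin_noiseless(scenarios):
    cfg = replace(scenarios["trypsin_paba"], snr_db=None)
    return cfg, generate_experiment_set(cfg)


@pytest.fixture(scope="session")
def thermolysin_noiseless(scenarios):
    cfg = replace(scenarios["thermolysin_phosphoramidon"], snr_db=None)
    return cfg, generate_experiment_set(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
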