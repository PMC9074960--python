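import numpy as np
import pytest

import osicea
from osicea.synthetic_data import IPDataset


@pytest.fixture(scope="session")
def base_config():
    """Packaged base-case configuration."""
    return osicea.load_config()


@pytest.fixture(scope="session")
def base_model(base_config):
    return base_config.cea_model()


@pytest.fixture(scope="session")
def base_outputs(base_model):
    """Evaluated base case: (placebo outputs, osimertinib outputs, CEAResult)."""
    return base_model.evaluate()


@pytest.fixture
def hand_ipd():
    """Five records: events at 1, 3, 5; censored at 2, 4.

    Product-limit by hand: S(1) = 4/5 = 0.8; at t=3 three remain, one event:
    S(3) = 0.8 * 2/3 = 8/15; at t=5 one remains: S(5) = 0.
    """
    return IPDataset(
        times=np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
        events=np.array([True, False, True, False, True]),
    )


HAND_KM = {1.0: 0.8, 3.0: 8.0 / 15.0, 5.0: 0.0}
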