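import numpy as np
import pandas as pd
import pytest

from subtypescreen import synthetic


@pytest.fixture(scope="session")
def base_config() -> synthetic.SimulationConfig:
    return synthetic.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def expression_and_labels(base_config):
    return synthetic.simulate_expression(base_config)


@pytest.fixture(scope="session")
def planted_screen(base_config, expression_and_labels):
    _, labels = expression_and_labels
    resp, sets, truth = synthetic.simulate_drug_response(base_config, labels, "viability")
    return resp, sets, truth, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
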