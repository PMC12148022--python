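import pytest

import respclim as rc


@pytest.fixture(scope="session")
def default_trace():
    """One noiseless simulated recording with its truth."""
    trace, truth = rc.simulate_trace(rc.TraceSimParams())
    return trace, truth


@pytest.fixture(scope="session")
def trait_data():
    """One synthetic trait table (paper-like design) prepared for modelling."""
    params = rc.TraitSimParams(seed=0)
    table, truth = rc.simulate_trait_table(params)
    return rc.prepare_traits(table), truth, params


@pytest.fixture(scope="session")
def sites16():
    return rc.simulate_climate_gradient(rc.TraitSimParams(seed=0))
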