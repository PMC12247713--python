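import pandas as pd
import pytest

from trnamod import calling
from trnamod.io import load_vocabulary
from trnamod.numbering import NumberingTemplate
from trnamod.simulate import SimulationConfig, simulate_scenario


@pytest.fixture(scope="session")
def template():
    return NumberingTemplate.standard()


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic scenario, fixed seed, shared across the suite."""
    return simulate_scenario(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def scenario_calls(scenario):
    return calling.call_modifications(scenario["coverage"],
                                      scenario["truth"])


def make_coverage(rows):
    """Coverage table from (species, trna, position, ref, a, c, g, t, d)."""
    return pd.DataFrame(rows, columns=[
        "species", "trna", "position", "ref_base",
        "count_a", "count_c", "count_g", "count_t", "count_del"])
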