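import numpy as np
import pytest

from neomer import (
    DEFAULT_TEMPLATE,
    PlantedBinder,
    SimulationConfig,
    parse_template,
    run_simulation,
)
from neomer.simulate import count_sample


@pytest.fixture(scope="session")
def paper_template():
    """The 74-character production template (16 N, 8 per module)."""
    return parse_template(DEFAULT_TEMPLATE)


@pytest.fixture(scope="session")
def toy_template():
    """Tiny symmetric template: 2+2 random positions around a GGCGCC site."""
    return parse_template("NNGGCGCCNN", restriction_site="GGCGCC")


BINDERS = (
    PlantedBinder("AAAA", "CCCC", 50.0),
    PlantedBinder("ACGT", "TGCA", 50.0),
    PlantedBinder("CCCC", "GGGG", 50.0),
    PlantedBinder("GGTT", "AATT", 50.0),
    PlantedBinder("TTTT", "TTTT", 50.0),
    PlantedBinder("GACT", "CTGA", 40.0, binds="resin"),
    PlantedBinder("TGCA", "GTAC", 40.0, binds="resin"),
)


@pytest.fixture(scope="session")
def small_sim():
    """One shared small-depth simulated experiment (target/naive/counter).

    Depth is kept modest so unit tests stay fast; the full-depth study
    conditions are exercised in the acceptance suite.
    """
    cfg = SimulationConfig(
        w_a=4, w_b=4, replicates=3, reads_per_sample=100_000,
        binders=BINDERS, counter_conditions=("resin",),
    )
    reads, truth = run_simulation(cfg, 20260921)
    return cfg, reads, truth


@pytest.fixture(scope="session")
def small_sim_tables(small_sim):
    """Module count tables for every sample of the shared simulation."""
    cfg, reads, _truth = small_sim
    tables = {}
    for condition, samples in reads.items():
        ta, tb = [], []
        for sample in samples:
            a, b = count_sample(sample, cfg)
            ta.append(a)
            tb.append(b)
        tables[condition] = (ta, tb)
    return tables


@pytest.fixture
def rng():
    return np.random.default_rng(7)
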