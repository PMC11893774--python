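import numpy as np
import pytest

from densimap.pipeline import build_plot_table
from densimap.synthetic import (GenerationConfig, generate_landscape,
                                generate_plots, generate_reference_db)

WORLD_SEED = 1


@pytest.fixture(scope="session")
def reference():
    return generate_reference_db(30, 120, 600, seed=WORLD_SEED)


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape((60, 60), seed=WORLD_SEED)


@pytest.fixture(scope="session")
def plots(landscape, reference):
    return generate_plots(landscape, reference,
                          GenerationConfig(seed=WORLD_SEED, n_plots=400))


@pytest.fixture(scope="session")
def world(landscape, reference, plots):
    """(table, matched_plots, landscape, reference) for the default world."""
    table, matched = build_plot_table(plots, reference, landscape)
    return table, matched, landscape, reference


@pytest.fixture(scope="session")
def plot_table(world):
    return world[0]


def majority(checks_by_seed):
    """True when checks pass for the majority of seeds (stochastic tests)."""
    results = list(checks_by_seed)
    return sum(bool(r) for r in results) > len(results) / 2
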