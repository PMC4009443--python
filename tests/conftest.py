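import numpy as np
import pytest

from seedgraph import (
    SimulationConfig,
    build_adjacency,
    preprocess_panel,
    simulate_study,
)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: raw panel with nuisance plus ground truth."""
    config = SimulationConfig(seed=7)
    panel, truth = simulate_study(config)
    return config, panel, truth


@pytest.fixture(scope="session")
def clean_panel(study):
    _, panel, _ = study
    return preprocess_panel(panel)


@pytest.fixture(scope="session")
def adjacency(clean_panel):
    return build_adjacency(clean_panel)


@pytest.fixture(scope="session")
def adjacency_positive(study, adjacency):
    _, _, truth = study
    pos = [n for n, s in zip(adjacency.node_ids, truth.sign_labels) if s > 0]
    return adjacency.select(pos)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
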