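import pytest

from mybkit.myb_identification import load_default_profile
from mybkit.synthetic_data import (
    DuplicationEvent,
    SimulationConfig,
    SsrPlanting,
    simulate_family_genome,
)


@pytest.fixture(scope="session")
def profile():
    return load_default_profile()


@pytest.fixture(scope="session")
def small_package():
    """One small genome with every planting type, shared across tests."""
    cfg = SimulationConfig(
        seed=11,
        n_chromosomes=2,
        genes_per_chromosome=8,
        n_expression_genes=300,
        duplication_events=[
            DuplicationEvent("tandem", 0.2, 0.5),
            DuplicationEvent("segmental", 0.15, 0.6),
        ],
        ssr_plantings=[
            SsrPlanting("AT", 7, "upstream"),
            SsrPlanting("AAG", 6, "genic"),
            SsrPlanting("ATTTTA", 7, "genic"),
        ],
    )
    return simulate_family_genome(cfg)
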