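import pytest

from panvita.io import GeneRecord
from panvita.synth import (
    SimulationConfig,
    simulate_evidence,
    simulate_pangenome,
)


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-noise 3-species × 2-strain cohort with evidence and truth."""
    config = SimulationConfig(seed=11)
    genomes, truth = simulate_pangenome(config)
    evidence = simulate_evidence(genomes, truth, config)
    return config, genomes, truth, evidence


@pytest.fixture
def toy_genome():
    """Five genes on one contig, in rank order."""
    return [
        GeneRecord(f"g{i}", "G1", "c1", i, "+", seq)
        for i, seq in enumerate(
            ["MKT" * 10, "MAV" * 10, "MLL" * 10, "MEE" * 10, "MWW" * 10]
        )
    ]
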