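import numpy as np
import pytest

from svforge import SimulationConfig, fixtures


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def toy_reference():
    """10 kb random reference."""
    return fixtures.make_reference(10_000, seed=42)


@pytest.fixture
def medium_reference():
    """100 kb random reference (complex-SV instantiation scale)."""
    return fixtures.make_reference(100_000, seed=43)


@pytest.fixture
def mixed_config():
    """About 50 mixed variants sized for a 10 kb reference."""
    return SimulationConfig(
        mode="uniform",
        counts={
            "TRA": 2, "INV": 3, "DUP": 3, "DEL": 8, "INS": 8,
            "SMALL_DEL": 8, "SMALL_INS": 8, "SNP": 10,
        },
        sv_length_range=(50, 150),
        seed=0,
    )
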