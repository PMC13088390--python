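import numpy as np
import pytest

from olivepedigree import GenotypeMatrix, simulate_dataset
from olivepedigree.config import CalibrationSettings, SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact panel: 40 founders, 2 bred generations, 96 loci."""
    return SimulationConfig(
        n_founders=40,
        n_loci=96,
        n_generations=2,
        crosses_per_generation=12,
        offspring_per_cross=2,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, n_validation=5)


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """Error-free variant of the compact panel."""
    return SimulationConfig(
        n_founders=40,
        n_loci=96,
        n_generations=2,
        crosses_per_generation=12,
        offspring_per_cross=2,
        error_rate=0.0,
        missing_rate=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return simulate_dataset(clean_config, n_validation=5)


@pytest.fixture(scope="session")
def fast_calibration() -> CalibrationSettings:
    """Reduced Monte-Carlo size for unit tests of calibration mechanics."""
    return CalibrationSettings(
        n_offspring=1200, n_candidate_parents=60, seed=5
    )


def matrix_from_rows(rows: dict[str, list[int]], loci=None) -> GenotypeMatrix:
    """Build a small genotype matrix from {id: dosages} (-1 = missing)."""
    ids = list(rows)
    data = np.array([rows[i] for i in ids], dtype=np.int8)
    if loci is None:
        loci = [f"L{j}" for j in range(data.shape[1])]
    return GenotypeMatrix(ids, loci, data)


def po_pairs(truth):
    """(parent, child) pairs from a truth table (in-panel parents only)."""
    out = []
    for _, row in truth.iterrows():
        for parent in (row["mother"], row["father"]):
            if isinstance(parent, str) and parent:
                out.append((parent, row["id"]))
    return out
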