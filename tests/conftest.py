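import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from palmssr.synthetic_data import (
    GenotypeConfig,
    LocusPlan,
    simulate_genotypes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_table(rng):
    """Three-group, 30-sample table over 12 polymorphic loci."""
    cfg = GenotypeConfig(
        group_sizes={"north": 10, "centre": 10, "south": 10},
        loci=[LocusPlan(n_alleles=3 + (j % 3), divergence=0.2) for j in range(12)],
        missing_rate=0.05,
    )
    table, truth = simulate_genotypes(cfg, rng)
    return table, truth
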