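import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from sansara.synthetic_data import (
    GeneKinetics,
    PopulationSpec,
    SimulationConfig,
    simulate_matched_expression_pair,
    simulate_steady_state,
)


@pytest.fixture(scope="session")
def small_sim():
    """One steady-state population: 300 cells x 30 genes, no dropout."""
    rng = np.random.default_rng(7)
    from sansara.synthetic_data import default_kinetics

    kin = default_kinetics(30, rng)
    cfg = SimulationConfig(
        populations=[PopulationSpec(300, kin, "pop0")], seed=7, dropout_rate=0.0
    )
    mat, labels = simulate_steady_state(cfg)
    return mat, labels, kin


@pytest.fixture(scope="session")
def matched_pair_small():
    """Two matched-total populations: 150+150 cells x 60 genes (15 designated)."""
    mat, labels = simulate_matched_expression_pair(
        n_cells_per_pop=150, n_genes=60, splice_shift=0.6, seed=3, n_designated=15
    )
    return mat, labels
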