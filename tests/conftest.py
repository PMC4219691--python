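import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from labnet import (
    Network,
    SimulationConfig,
    generate_gold_network,
    simulate_expression,
    standardize,
)


@pytest.fixture(scope="session")
def small_benchmark():
    """A 20-gene scale-free benchmark with standardized expression."""
    config = SimulationConfig(p=20, n=80, seed=11)
    gold = generate_gold_network(config)
    matrix = simulate_expression(gold, config)
    return gold, standardize(matrix), config


def chain_network(p: int) -> Network:
    """Path graph G1 - G2 - ... - Gp as an undirected Network."""
    adjacency = np.zeros((p, p), dtype=int)
    for i in range(p - 1):
        adjacency[i, i + 1] = adjacency[i + 1, i] = 1
    return Network(
        gene_ids=[f"G{i + 1}" for i in range(p)],
        adjacency=adjacency,
        directed=False,
    )
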