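from __future__ import annotations

import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from netpharm.synthetic import SyntheticBundle, gen_bundle


@pytest.fixture(scope="session")
def bundle() -> SyntheticBundle:
    """One paper-scale synthetic bundle shared across tests (seed 7)."""
    return gen_bundle(7)


def random_graph(seed: int, n_max: int = 30, n_min: int = 4, labels: bool = True) -> nx.Graph:
    """A random Gnp graph with seeded size and density (may be disconnected)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.1, 0.6))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    if labels:
        g = nx.relabel_nodes(g, {v: f"G{v:03d}" for v in g.nodes})
    return g
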