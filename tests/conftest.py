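import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from activepath.io_formats import GeneSetCollection, IntensityStudy, PPINetwork, ProteinGeneMap


@pytest.fixture
def tiny_study() -> IntensityStudy:
    """3 proteins x 8 samples, two groups, one missing cell."""
    rng = np.random.default_rng(0)
    intensities = rng.uniform(50, 150, size=(3, 8))
    intensities[0, 0] = np.nan
    samples = [f"S{i}" for i in range(8)]
    groups = {s: ("CASE" if i < 4 else "CONTROL") for i, s in enumerate(samples)}
    return IntensityStudy(
        protein_ids=["P1", "P2", "P3"],
        sample_ids=samples,
        intensities=intensities,
        groups=groups,
    )


@pytest.fixture
def path_network() -> PPINetwork:
    """20-node path graph A00-A19."""
    nodes = [f"A{i:02d}" for i in range(20)]
    return PPINetwork.from_edges(zip(nodes, nodes[1:]))


@pytest.fixture
def small_collection() -> GeneSetCollection:
    return GeneSetCollection(
        {
            "KEGG:04614": ("RAS", frozenset({"AGT", "MAS1"})),
            "KEGG:04610": ("CCC", frozenset({"KNG1", "C7", "A2M", "SERPINE1"})),
        }
    )


@pytest.fixture(scope="session")
def bench7():
    """Shared default benchmark (seed 7) for expensive integration tests."""
    from activepath.synthetic import generate_benchmark

    return generate_benchmark(seed=7)
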