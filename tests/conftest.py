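import networkx as nx
import numpy as np
import pytest

from contactscape.genome import BinGrid, Genome
from contactscape.matrix import ContactMatrix


@pytest.fixture
def genome():
    """Two 5 Mb chromosomes plus a third for inter-chromosomal cases."""
    return Genome({"chr1": 5_000_000, "chr2": 5_000_000, "chr5": 5_000_000})


@pytest.fixture
def grid3():
    return BinGrid("chr1", 3_000_000, 1_000_000)


def make_intra(values, chrom="chr1", resolution=1_000_000, **kwargs):
    values = np.asarray(values, dtype=float)
    grid = BinGrid(chrom, values.shape[0] * resolution, resolution)
    return ContactMatrix(grid, grid, values, **kwargs)


@pytest.fixture
def random_graphs():
    """Assorted small random graphs (dense, sparse, disconnected)."""
    def factory(count, max_nodes=25, seed=0):
        rng = np.random.default_rng(seed)
        graphs = []
        for _ in range(count):
            n = int(rng.integers(4, max_nodes + 1))
            p = float(rng.uniform(0.08, 0.35))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            graphs.append(g)
        return graphs
    return factory
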