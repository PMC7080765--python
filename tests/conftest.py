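import networkx as nx
import numpy as np
import pytest

from chipsmith.genotype_qc import GenotypeMatrix
from chipsmith.simulate import CatalogSpec, simulate_genome_and_catalog


@pytest.fixture(scope="session")
def small_catalog():
    """23-gene synthetic catalog spanning all five categories."""
    genome, models, catalog = simulate_genome_and_catalog(CatalogSpec(), seed=11)
    return genome, models, catalog


@pytest.fixture
def toy_matrix():
    """4 samples x 5 SNPs with one missing and one heterozygous call."""
    calls = np.array(
        [
            [0, 0, 2, 1, 0],
            [0, 2, 2, 0, 0],
            [2, 2, 0, 0, -1],
            [2, 0, 0, 2, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        samples=["s1", "s2", "s3", "s4"],
        snps=[f"snp{i}" for i in range(1, 6)],
        calls=calls,
        snp_meta={
            "chrom": ["LG1", "LG1", "LG1", "LG2", "LG2"],
            "pos": [100, 5000, 9900, 100, 9900],
            "ref": list("ACGTA"),
            "alt": list("GTACC"),
        },
    )


def random_additive_tree(n_tips: int, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """A random binary tree metric: returns (tip distance matrix, tip names).

    Built by repeatedly splitting a random edge and hanging a new tip, with
    branch lengths bounded away from zero so the realizing topology is
    unique.
    """
    t = nx.Graph()
    for i in range(3):
        t.add_edge(f"t{i}", "c", weight=rng.uniform(0.1, 1.0))
    internal = 0
    for k in range(3, n_tips):
        u, v = list(t.edges)[int(rng.integers(t.number_of_edges()))]
        w = t.edges[u, v]["weight"]
        t.remove_edge(u, v)
        internal += 1
        mid = f"i{internal}"
        s = rng.uniform(0.2, 0.8)
        t.add_edge(u, mid, weight=w * s)
        t.add_edge(v, mid, weight=w * (1 - s))
        t.add_edge(f"t{k}", mid, weight=rng.uniform(0.1, 1.0))
    tips = [f"t{i}" for i in range(n_tips)]
    sp = dict(nx.all_pairs_dijkstra_path_length(t))
    d = np.array([[sp[a][b] for b in tips] for a in tips])
    return d, tips
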