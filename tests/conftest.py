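import networkx as nx
import numpy as np
import pytest

from edura.genome_networks import CircularGenome, GeneRecord


def point_genome(centers, g):
    """Genome of point genes (start = end = centre) at given coordinates."""
    records = [
        GeneRecord(f"g{i}", int(c), int(c), float(c))
        for i, c in enumerate(centers)
    ]
    return CircularGenome(g, records)


def digraph(edges, nodes=None):
    graph = nx.DiGraph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    graph.add_edges_from(edges)
    return graph


@pytest.fixture
def toy_genome():
    """Six point genes on a circle of 100 bp."""
    return point_genome([5, 20, 35, 55, 70, 90], 100)


@pytest.fixture
def toy_trn(toy_genome):
    return digraph(
        [("g0", "g1"), ("g1", "g2"), ("g3", "g4"), ("g4", "g0"),
         ("g5", "g2"), ("g2", "g5")],
        nodes=toy_genome.gene_ids,
    )


def random_embedded_graph(rng, n_genes=None, n_edges=None, g=100_000):
    """Random toy embedding: <= 30 genes, <= 60 edges, integer centres."""
    n_genes = n_genes or int(rng.integers(5, 31))
    n_edges = n_edges or int(rng.integers(5, 61))
    centers = rng.choice(g, size=n_genes, replace=False)
    genome = point_genome(centers, g)
    ids = genome.gene_ids
    edges = set()
    while len(edges) < min(n_edges, n_genes * (n_genes - 1)):
        i, j = rng.integers(n_genes, size=2)
        if i != j:
            edges.add((ids[i], ids[j]))
    return genome, digraph(sorted(edges), nodes=ids)
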