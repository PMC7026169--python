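"""Null models: switch randomization and planted-axis systematic networks.

``switch_randomize`` rewires a directed graph by repeated double-edge swaps
(a->b, c->d) => (a->d, c->b), preserving every node's in- and out-degree
exactly while destroying higher-order structure.  Gene positions are not
touched, so the randomized graph can be rescanned in the same embedding.

``generate_systematic_network`` plants an Ori–Ter axis into a random graph:
N/2 gene positions per arm, then exactly the requested number of edges in
each of the six categories relative to the planted axis.  Recounting the
categories at the planted axis reproduces the request — the generator is
the calibration tool for the axis-detection statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .genome_networks import CircularGenome, GeneRecord
from .scan import AxisPosition, CategoryCounts

logger = logging.getLogger(__name__)


class NullModelError(ValueError):
    pass


@dataclass(frozen=True)
class RandomizationConfig:
    n_steps: int = 5000          # accepted swaps; rejections do not count
    seed: int | None = None
    max_attempt_factor: int = 100

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise NullModelError("n_steps must be >= 0")


def switch_randomize(graph: nx.DiGraph, config: RandomizationConfig) -> nx.DiGraph:
    """Degree-preserving rewiring by ``n_steps`` accepted double-edge swaps.

    Swaps creating self-loops or duplicate edges are rejected and do not
    count towards ``n_steps``.  Attempts are capped at
    ``max_attempt_factor * n_steps`` to avoid livelock on rigid graphs.
    """
    out = graph.copy()
    if out.number_of_edges() < 2 or config.n_steps == 0:
        if out.number_of_edges() < 2:
            logger.warning("switch_randomize: fewer than 2 edges, returning copy")
        return out
    rng = np.random.default_rng(config.seed)
    edges = list(out.edges())
    edge_set = set(edges)
    n_edges = len(edges)
    accepted = 0
    attempts = 0
    cap = config.max_attempt_factor * config.n_steps
    while accepted < config.n_steps:
        if attempts >= cap:
            raise NullModelError(
                f"switch_randomize: only {accepted}/{config.n_steps} swaps "
                f"accepted after {attempts} attempts"
            )
        attempts += 1
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1
    result = nx.DiGraph()
    result.add_nodes_from(out.nodes())
    result.add_edges_from(edges)
    return result


@dataclass(frozen=True)
class SystematicNetworkSpec:
    """Parameters of the planted-axis generator.

    ``n_nodes`` genes (N even) are placed N/2 per arm of the axis at ``axis``
    on a circle of ``genome_length`` (even) base pairs; then exactly
    ``category_counts`` edges are drawn per category relative to that axis.
    """

    n_nodes: int
    category_counts: CategoryCounts
    axis: AxisPosition
    genome_length: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_nodes % 2 != 0 or self.n_nodes < 2:
            raise NullModelError(f"n_nodes must be even and >= 2, got {self.n_nodes}")
        if self.genome_length % 2 != 0:
            raise NullModelError("genome_length must be even (arm boundary at g/2)")
        if self.n_nodes // 2 > self.genome_length // 2 - 1:
            raise NullModelError("genome too short for distinct per-arm positions")


def _sample_pairs(rng, pairs_src, pairs_dst, count, category):
    n_avail = len(pairs_src)
    if count > n_avail:
        raise NullModelError(
            f"category {category}: requested {count} edges but only "
            f"{n_avail} ordered pairs available"
        )
    if count == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    pick = rng.choice(n_avail, size=count, replace=False)
    return pairs_src[pick], pairs_dst[pick]


def generate_systematic_network(
    spec: SystematicNetworkSpec,
) -> tuple[CircularGenome, nx.DiGraph]:
    """Generate a genome + directed graph with planted category counts.

    Point genes (start = end = centre) sit strictly inside each arm, so no
    gene falls on the axis itself.  Per category, the requested number of
    distinct ordered pairs is drawn uniformly among all pairs realising that
    category at the planted axis; recounting at the axis reproduces the
    request exactly.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.genome_length
    half = g // 2
    n_arm = spec.n_nodes // 2
    ori = spec.axis.ori_bp
    # distinct integer offsets strictly inside (0, g/2) per arm
    off_r = rng.choice(half - 1, size=n_arm, replace=False) + 1
    off_l = rng.choice(half - 1, size=n_arm, replace=False) + 1
    pos_r = (ori + np.sort(off_r)) % g          # sorted by distance to Ori
    pos_l = (ori + half + np.sort(off_l)) % g
    ids_r = np.array([f"g{i:04d}" for i in range(n_arm)], dtype=object)
    ids_l = np.array([f"g{i + n_arm:04d}" for i in range(n_arm)], dtype=object)

    c = spec.category_counts
    iu, ju = np.triu_indices(n_arm, k=1)        # i closer to Ori than j
    grid_r, grid_l = np.meshgrid(np.arange(n_arm), np.arange(n_arm), indexing="ij")
    grid_r, grid_l = grid_r.ravel(), grid_l.ravel()

    edges: list[tuple[str, str]] = []
    for count, cat, src_ids, dst_ids, src_idx, dst_idx in (
        (c.n_r_plus, "r+", ids_r, ids_r, iu, ju),
        (c.n_r_minus, "r-", ids_r, ids_r, ju, iu),
        # left-arm offsets run forward from Ter, so a larger offset is
        # *closer* to Ori: the away-from-Ori direction is j -> i
        (c.n_l_plus, "l+", ids_l, ids_l, ju, iu),
        (c.n_l_minus, "l-", ids_l, ids_l, iu, ju),
        (c.n_rl, "rl", ids_r, ids_l, grid_r, grid_l),
        (c.n_lr, "lr", ids_l, ids_r, grid_l, grid_r),
    ):
        si, di = _sample_pairs(rng, src_idx, dst_idx, count, cat)
        edges.extend(zip(src_ids[si], dst_ids[di]))

    records = [
        GeneRecord(gid, int(p), int(p), float(p))
        for gid, p in zip(np.concatenate([ids_r, ids_l]),
                          np.concatenate([pos_r, pos_l]))
    ]
    genome = CircularGenome(g, records)
    graph = nx.DiGraph()
    graph.add_nodes_from(genome.gene_ids)
    graph.add_edges_from(edges)
    return genome, graph


def sample_node_subsets(
    universe, k: int, n_draws: int, seed: int | None = None
) -> list[list]:
    """``n_draws`` uniform without-replacement subsets of size k."""
    universe = list(universe)
    if k > len(universe):
        raise NullModelError(f"k={k} exceeds universe size {len(universe)}")
    if k < 0:
        raise NullModelError("k must be >= 0")
    rng = np.random.default_rng(seed)
    arr = np.array(universe, dtype=object)
    return [list(arr[rng.choice(len(arr), size=k, replace=False)])
            for _ in range(n_draws)]


def sample_index_subsets(
    n_universe: int, k: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_draws, k) index matrix of uniform without-replacement subsets."""
    if k > n_universe:
        raise NullModelError(f"k={k} exceeds universe size {n_universe}")
    out = np.empty((n_draws, k), dtype=np.int64)
    for i in range(n_draws):
        out[i] = rng.choice(n_universe, size=k, replace=False)
    return out
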