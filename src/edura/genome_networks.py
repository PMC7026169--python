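"""Circular genome model, table I/O, and construction of the TRN and GPN.

The chromosome is modelled as a circle of ``length_bp`` base pairs; every
gene is reduced to its centre coordinate (the midpoint of its start and end
positions).  Two graphs live on this coordinate system:

* the **TRN** (transcriptional regulatory network), a directed graph with an
  edge ``a -> b`` whenever the product of gene *a* regulates gene *b*;
* the **GPN** (gene proximity network), an undirected graph connecting genes
  whose centres lie within a circular distance threshold ``T_GPN``.

Coordinates are 0-based with inclusive start/end; all arithmetic is mod g.
Wrap-around genes (start > end) take the midpoint of the forward arc through
the origin.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default genome length: E. coli K-12 MG1655 chromosome (bp).
DEFAULT_GENOME_LENGTH = 4_641_652


class GenomeError(ValueError):
    """Invalid genome, coordinate or parse problem."""


def circular_distance(a: float, b: float, g: float) -> float:
    """Shortest arc distance between two coordinates on a circle of length g.

    Returns ``min(|a - b|, g - |a - b|)``; the result lies in ``[0, g/2]``.
    """
    if g <= 0:
        raise GenomeError(f"genome length must be positive, got {g}")
    d = abs(a - b)
    return min(d, g - d)


def circular_distance_array(a, b, g):
    """Vectorised :func:`circular_distance` for numpy arrays."""
    if g <= 0:
        raise GenomeError(f"genome length must be positive, got {g}")
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    return np.minimum(d, g - d)


def gene_center(start: float, end: float, g: float) -> float:
    """Centre of a gene: the average of its start and end positions.

    Genes wrapping through the origin (start > end) use the midpoint of the
    forward arc from start through the origin to end, reduced mod g.
    """
    if g <= 0:
        raise GenomeError(f"genome length must be positive, got {g}")
    if start <= end:
        return (start + end) / 2.0
    return ((start + end + g) / 2.0) % g


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    start_bp: int
    end_bp: int
    center_bp: float

    @classmethod
    def make(cls, gene_id: str, start_bp: int, end_bp: int, g: int) -> "GeneRecord":
        return cls(gene_id, start_bp, end_bp, gene_center(start_bp, end_bp, g))


@dataclass
class CircularGenome:
    """A circular chromosome of ``length_bp`` base pairs carrying genes."""

    length_bp: int
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise GenomeError(f"genome length must be positive, got {self.length_bp}")
        seen: set[str] = set()
        for rec in self.genes:
            if rec.gene_id in seen:
                raise GenomeError(f"duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)
            for coord in (rec.start_bp, rec.end_bp):
                if not (0 <= coord < self.length_bp):
                    raise GenomeError(
                        f"gene {rec.gene_id!r}: coordinate {coord} outside "
                        f"[0, {self.length_bp})"
                    )

    @property
    def gene_ids(self) -> list[str]:
        return [rec.gene_id for rec in self.genes]

    @property
    def centers(self) -> dict[str, float]:
        return {rec.gene_id: rec.center_bp for rec in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return any(rec.gene_id == gene_id for rec in self.genes)


def load_genome(path, length_bp: int = DEFAULT_GENOME_LENGTH) -> CircularGenome:
    """Read an annotation TSV (gene_id, start, end) into a CircularGenome.

    The table is tab-separated with a header; '#' lines are comments.  The
    genome length comes from configuration, not from the coordinates.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    required = {"gene_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        gid = str(row.gene_id)
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise GenomeError(f"{path} row {i}: non-integer coordinates") from exc
        if gid in seen:
            raise GenomeError(f"{path} row {i}: duplicate gene_id {gid!r}")
        seen.add(gid)
        records.append(GeneRecord.make(gid, start, end, length_bp))
    return CircularGenome(length_bp, records)


def write_genome(genome: CircularGenome, path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in genome.genes],
            "start": [r.start_bp for r in genome.genes],
            "end": [r.end_bp for r in genome.genes],
        }
    ).to_csv(path, sep="\t", index=False)


def load_trn(path, genome: CircularGenome) -> nx.DiGraph:
    """Read a two-column (regulator, target) edge list into a directed TRN.

    Edges touching genes absent from the genome are dropped (count logged);
    duplicate edges collapse.  Self-loops are retained at load time — each
    analysis states its own exclusion rule.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise GenomeError(f"{path}: expected two columns (regulator, target)")
    known = set(genome.gene_ids)
    graph = nx.DiGraph()
    graph.add_nodes_from(gid for gid in genome.gene_ids)
    dropped = 0
    for src, dst in df.iloc[:, :2].itertuples(index=False):
        if src in known and dst in known:
            graph.add_edge(src, dst)
        else:
            dropped += 1
    if dropped:
        logger.warning("load_trn: dropped %d edge(s) with unknown genes", dropped)
    # restrict node set to genes actually present (all of them, by construction)
    return graph


def write_edges(graph: nx.DiGraph, path) -> None:
    pd.DataFrame(graph.edges(), columns=["regulator", "target"]).to_csv(
        path, sep="\t", index=False
    )


def load_operon_map(path) -> dict[str, str]:
    """Read a gene_id -> operon_id TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene_id", "operon_id"} <= set(df.columns):
        raise GenomeError(f"{path}: need columns gene_id, operon_id")
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise GenomeError(
            f"{path}: gene(s) mapped to multiple operons: "
            f"{sorted(df.loc[dup, 'gene_id'])[:5]}"
        )
    return dict(zip(df["gene_id"], df["operon_id"]))


def load_binding_sites(path) -> np.ndarray:
    """Read a BED-like TSV of single-bp site centres; returns positions."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "position" not in df.columns:
        raise GenomeError(f"{path}: need a 'position' column")
    return df["position"].to_numpy(dtype=float)


def build_gpn(genome: CircularGenome, threshold_bp: int) -> nx.Graph:
    """Gene proximity network: edge iff circular centre distance <= threshold.

    The threshold is inclusive.  Node set = all genes.  Uses a sorted sliding
    window on the circle, O(N log N + E).
    """
    if threshold_bp < 0:
        raise GenomeError(f"threshold_bp must be >= 0, got {threshold_bp}")
    g = genome.length_bp
    graph = nx.Graph()
    graph.add_nodes_from(genome.gene_ids)
    n = len(genome)
    if n < 2:
        return graph
    ids = np.array(genome.gene_ids, dtype=object)
    centers = np.array([r.center_bp for r in genome.genes], dtype=float)
    order = np.argsort(centers, kind="stable")
    ids, centers = ids[order], centers[order]
    # doubled array handles the wrap; pair (i, j) added once with i < j in ring
    ext = np.concatenate([centers, centers + g])
    for i in range(n):
        j = np.searchsorted(ext, centers[i] + threshold_bp, side="right")
        for k in range(i + 1, j):
            partner = k % n
            if partner == i:
                continue
            # guard antipodal over-reach when threshold > g/2
            if circular_distance(centers[i], centers[partner], g) <= threshold_bp:
                graph.add_edge(ids[i], ids[partner])
    return graph


def collapse_to_operons(trn: nx.DiGraph, operons: Mapping[str, str]) -> nx.DiGraph:
    """Collapse a gene-level TRN to operon level.

    Operon O1 -> O2 iff some gene-level edge a -> b has a in O1, b in O2 and
    O1 != O2; within-operon edges vanish.
    """
    unmapped = [n for n in trn.nodes if n not in operons]
    if unmapped:
        raise GenomeError(f"genes not covered by operon map: {sorted(unmapped)[:10]}")
    out = nx.DiGraph()
    out.add_nodes_from(set(operons[n] for n in trn.nodes))
    for a, b in trn.edges:
        oa, ob = operons[a], operons[b]
        if oa != ob:
            out.add_edge(oa, ob)
    return out


def circular_mean_position(positions, g: float) -> float:
    """Mean of coordinates on the circle (vector average of angles)."""
    theta = np.asarray(positions, dtype=float) * (2 * np.pi / g)
    mean = np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta)))
    return float((mean * g / (2 * np.pi)) % g)


def operon_genome(genome: CircularGenome, operons: Mapping[str, str]) -> CircularGenome:
    """Operon-level genome: each operon at the circular mean of its member
    gene centres (point records)."""
    members: dict[str, list[float]] = {}
    centers = genome.centers
    for gene_id, op in operons.items():
        if gene_id in centers:
            members.setdefault(op, []).append(centers[gene_id])
    records = []
    for op in sorted(members):
        c = circular_mean_position(members[op], genome.length_bp)
        coord = int(c) % genome.length_bp
        records.append(GeneRecord(op, coord, coord, c))
    return CircularGenome(genome.length_bp, records)


def _total_degrees(graph) -> dict:
    return dict(graph.degree())


def _assortativity_total_degree(graph) -> float:
    """Pearson correlation of total degrees over edge endpoint pairs.

    Each edge contributes both orientations, the undirected convention.
    NaN for graphs with < 2 edges or zero degree variance.
    """
    deg = _total_degrees(graph)
    if graph.number_of_edges() < 2:
        return float("nan")
    xs, ys = [], []
    for u, v in graph.edges():
        xs.extend((deg[u], deg[v]))
        ys.extend((deg[v], deg[u]))
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


@dataclass
class GraphSummary:
    n_nodes: int
    n_edges: int
    min_degree: int
    max_degree: int
    mean_total_degree: float
    largest_component_nodes: int
    largest_component_edges: int
    degree_assortativity: float
    degree_assortativity_largest_component: float

    def to_json(self) -> str:
        return json.dumps(
            {
                k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in self.__dict__.items()
            },
            indent=2,
        )


def graph_summary(graph) -> GraphSummary:
    """Basic census of a graph: size, degree statistics, largest component.

    ``mean_total_degree`` is 2E/N (total = in + out for directed graphs).
    Components are weakly connected for directed graphs.  Assortativity is
    reported for the full graph and for its largest component.
    """
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    if n == 0:
        return GraphSummary(0, 0, 0, 0, float("nan"), 0, 0, float("nan"), float("nan"))
    degs = [d for _, d in graph.degree()]
    if graph.is_directed():
        comps = nx.weakly_connected_components(graph)
    else:
        comps = nx.connected_components(graph)
    largest = max(comps, key=len)
    sub = graph.subgraph(largest)
    return GraphSummary(
        n_nodes=n,
        n_edges=e,
        min_degree=min(degs),
        max_degree=max(degs),
        mean_total_degree=2.0 * e / n,
        largest_component_nodes=sub.number_of_nodes(),
        largest_component_edges=sub.number_of_edges(),
        degree_assortativity=_assortativity_total_degree(graph),
        degree_assortativity_largest_component=_assortativity_total_degree(sub),
    )
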